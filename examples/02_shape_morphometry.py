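"""Roundness and roughness of smooth versus protrusive cell footprints.

Roundness = 4*area / (pi * MA^2) is 1 for a circle and drops for
elongated cells; roughness = perimeter / hull perimeter is 1 for convex
footprints and grows with boundary protrusions.  Together they separate
smooth, symmetric synapses from irregular ones.
"""

from synapsekit import make_rough_mask, shape_metrics
from synapsekit.segmentation import mask_to_cell

shapes = {
    "disk (r=50 px)": make_rough_mask((50.0, 50.0)),
    "2:1 ellipse": make_rough_mask((60.0, 30.0)),
    "protrusive (eps=0.3, 8 lobes)": make_rough_mask((40.0, 40.0), 0.3, 8, seed=2),
}

print(f"{'shape':32s} {'roundness':>9s} {'roughness':>9s} {'MA (px)':>8s}")
for name, mask in shapes.items():
    m = shape_metrics(mask_to_cell(mask), cell_id=name)
    print(f"{name:32s} {m.roundness:9.3f} {m.roughness:9.3f} {m.major_axis_px:8.1f}")

print(
    "\nThe disk sits at roundness ~1 / roughness ~1; the ellipse keeps a"
    "\nsmooth boundary (roughness ~1) but roundness ~0.5; the lobed mask"
    "\nstays round overall yet its roughness rises well above 1."
)
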