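"""F-actin line profiles across a synapse with a peripheral actin ring.

A mature synapse accumulates F-actin in a peripheral ring and clears it
centrally (where lytic granules are secreted).  Sampling intensity along
lines through the cell center at several angles turns that pattern into
two symmetric peaks with a central valley.
"""

import numpy as np

from synapsekit import SyntheticCellSpec, factin_profiles, make_conjugate_image, segment_cell

spec = SyntheticCellSpec(seed=7, noise_sigma=2.0)
channels, truth = make_conjugate_image((0.0, 0.0), None, spec)
cell = segment_cell(channels["cd8"])

for prof in factin_profiles(channels["actin"], cell, [0.0, 45.0, 90.0, 135.0]):
    peaks = prof.peak_positions()
    center_val = prof.intensities[np.argmin(np.abs(prof.positions_um))]
    print(
        f"angle {prof.angle_deg:5.1f} deg: ring peaks at "
        f"{np.array2string(peaks, precision=2)} um, "
        f"peak/center intensity ratio {prof.intensities.max() / center_val:.1f}"
    )

print(
    "\nTwo peaks at +-(cell radius) with a high peak/center ratio at every"
    "\nangle indicate a cleared F-actin ring; a filled synapse would show"
    "\na flat or single-peaked profile instead."
)
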