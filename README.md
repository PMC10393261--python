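# synapsekit

Quantitative image analysis of T-cell immunological synapses from
single-cell fluorescence microscopy.

When a cytotoxic T lymphocyte (CTL) engages a target — or spreads on an
antibody-coated coverslip forming a flat pseudo-synapse — its cytoskeleton
reorganises: microtubules form a radial array emanating from the
centrosome, F-actin accumulates in a peripheral ring with central
clearance, and the centrosome docks near the synapse center. `synapsekit`
turns each of these hallmarks into a number, so that cells from different
donors or conditions can be compared statistically:

* **Degree of Radiality (DoR)** of the microtubule network. Per-pixel
  filament orientation `t(p)` is estimated with a structure tensor; the
  cell's convex-hull interior is partitioned into `K` concentric radial
  sections bounded by scaled elliptical-Fourier contours of the hull
  boundary; and per section `s`

  ```
  DoR(s) = Σ_p |t(p)·r̂(p)| / max( Σ_p |t(p)·ĉ(p)|, ε )
  ```

  with `r̂`/`ĉ` the unit radial/circular fields about the hull centroid.
  DoR > 1 = radial (organised) network, DoR < 1 = tangential, DoR = 1 = no
  preference. The profile is reported against the relative radial distance
  from the cell center (section index, innermost = 1).
* **Morphometry**: roundness `4·area/(π·MA²)` (MA = major axis of the
  moment-equivalent ellipse) and roughness `P/P_hull` (4-direction Crofton
  perimeter of the mask over that of its convex hull).
* **Centrosome polarization**: in-plane distance (µm) between the
  pericentrin punctum and the synapse center, binned ≤1 / 1–3 / >3 µm.
* **F-actin line profiles** through the cell center at several angles,
  turning ring-vs-filled actin layouts into peak/valley patterns.
* **Group statistics**: per-cell metrics compared with Student's t or
  Mann–Whitney U, plus box-plot reporting.

Because raw confocal data for this assay are rarely shareable, the package
includes a seeded synthetic-image generator (`synapsekit.synthetic`) that
renders filament networks, actin rings and centrosome puncta with exact
ground truth — every stage of the pipeline is validated against it.

## Worked example

```python
from synapsekit import SyntheticCellSpec, dor_at, dor_profile, make_filament_cell

spec = SyntheticCellSpec(radiality_alpha=1.0, seed=42)   # radial network
image, truth = make_filament_cell(spec)
profile = dor_profile(image)
print(profile.to_frame())
print("DoR at relative distance 2:", round(dor_at(profile, 2.0), 2))
```

prints

```
  cell_id  section  relative_distance  n_pixels       dor
0    cell        1                1.0       280  1.513218
1    cell        2                2.0       856  3.941549
2    cell        3                3.0      1428  6.895852
3    cell        4                4.0      1996  1.622480
DoR at relative distance 2: 3.94
```

DoR well above 1 in the interior sections identifies a radially organised
microtubule array; rerunning with `radiality_alpha=0.2` (a disorganised
network) yields DoR ≈ 0.66 at the same distance. The outermost section is
systematically pulled toward 1 by the cell's own boundary edge, which the
structure tensor reads as a tangential structure (see
`docs/methods.md`). The `examples/` directory holds one short script per
capability (simulation + DoR, morphometry, centrosome distances, F-actin
profiles, group comparison); each prints its numbers with a line on what
they mean. A thin CLI (`synapsekit simulate|segment|dor|morph|synapse|profiles|compare`)
wraps the same functions for batch use on TIFF folders.

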