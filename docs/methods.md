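# Methods

This note documents the measurements implemented in `synapsekit`, the
assumptions behind them, the synthetic data they are validated on, and
the numerical choices that were genuinely open.

## Coordinate and unit conventions

All rasters use 0-based `(row, col)` indices with the row axis pointing
down. Physical distances are pixel displacements multiplied by the
image's `pixel_size_um`. Axial angles (orientations defined modulo π)
are measured from the column axis, so the unit direction vector of angle
θ is `(sin θ, cos θ)`; θ = 0 is a horizontal structure. Intensities are
never rescaled on load: the downstream operators (Otsu threshold,
structure tensor, DoR) are invariant to a global positive intensity
scale, and silent normalisation would change thresholds.

## Segmentation and the cell center

Cells are segmented by a global Otsu threshold on the raw image;
8-connected components smaller than `min_area_px` (default 100 px — the
method only requires "small" debris removal, and 100 px ≈ 1 µm² at the
default sampling) are discarded, and if several components survive the
largest is kept: the pipeline analyses one cell per crop, and keeping
the largest avoids silently merging neighbours. The cell *center* used
by every radial measurement is the centroid of the **filled convex
hull** of the mask (not of the mask itself, and not of the hull's
boundary polygon): the hull centroid is insensitive to intensity
asymmetries and boundary protrusions of the cell body.

## Degree of Radiality

1. **Orientation.** The structure tensor (Gaussian gradient and
   integration scale `sigma_px`, default 1.5 px — about half a filament
   width at 0.1 µm/px) is computed with reflective boundary handling.
   The reported angle is the orientation of the eigenvector of the
   smaller eigenvalue, i.e. the direction *along* the local stripe.
   Coherence `(λ₁−λ₂)/(λ₁+λ₂)` is 0 in flat regions and 1 for a perfect
   stripe; pixels with a vanishing tensor get coherence 0.
2. **Reference fields.** Unit radial and circular fields about the hull
   centroid, defined on hull pixels farther than 1 px from the center.
   The circular field is the radial field rotated +90°
   (counter-clockwise in row-down coordinates); the sign is a fixed
   convention and cannot affect results because only absolute dot
   products enter the statistic.
3. **Radial sections.** An elliptical Fourier descriptor (EFD, 10
   harmonics by default) is fitted to the hull boundary; intermediate
   contours are the outer contour scaled about the center by `k/K`
   (default `K = 4`), and section `k` is the region between contours
   `k−1` and `k`, with points exactly on contour `k` assigned to section
   `k` and hull pixels marginally outside the fitted outer contour
   clamped to section K so the sections exactly tile the hull interior
   minus the 1-px center disk. The *relative radial distance* of section
   `k` is the integer `k` itself (contour-spacing units from the
   center); "DoR at relative distance 2" therefore denotes the second
   section. This normalisation is a documented package convention —
   exposed via `K` and the queried distance — since no unique convention
   is standard.
4. **The statistic.** Per section, DoR = Σ|t·r̂| / max(Σ|t·ĉ|, ε) over
   valid pixels. By default every hull pixel is valid
   (`coherence_min = 0`, the least-committal choice); raising
   `coherence_min` restricts the sums to clearly oriented pixels, which
   sharpens the statistic when backgrounds are noisy. ε defaults to
   10⁻⁶ × (valid pixels in the section), keeping the purely radial limit
   finite and the statistic independent of cell size; passing an
   explicit ε uses it as an absolute guard.

Limits: a purely radial field gives DoR = N/ε, purely tangential gives
0, a field everywhere at 45° to the radius gives exactly 1, and
uniformly random axial angles converge to 1 (E|cos| = E|sin|).

### EFD details

The descriptors use the arc-length (Kuhl–Giardina) parametrisation of
the closed hull contour. One consequence worth knowing: an ellipse
traversed at uniform speed is *not* a pure first harmonic — the first
harmonic of a 2:1 ellipse has an axis ratio of only ≈1.7 — but the full
10-harmonic reconstruction recovers hull boundaries to well under a
pixel (tests assert mean point-to-boundary distance < 1 px), which is
what the section geometry depends on.

### Known limitation: the boundary edge

The intensity step at the cell outline is itself a genuine, highly
coherent *tangential* structure. With `coherence_min = 0` it pulls the
outermost section's DoR toward (and below) its interior value even for
perfectly radial filament networks — on synthetic radial cells the
outer section reads ≈1.6 where interior sections read 4–7. This affects
real images equally; comparisons should therefore either use interior
sections (the default readout at relative distance 2 is one) or raise
`coherence_min` and mask the boundary.

## Morphometry

Roughness is `P/P_hull` with both perimeters estimated by the same
4-direction Crofton method so their shared discretisation bias largely
cancels — convex masks measure 1.00 ± 0.02. The Crofton estimator
itself underestimates long axis-aligned straight edges by ≈5.5%
(verified at several scales); this bias is irrelevant for the ratio and
small for blob-like cells. Roundness is `4·area/(π·MA²)` with MA = 4·√
(largest eigenvalue of the normalised second central moment matrix),
computed via `skimage.measure.regionprops`; it is rotation- and
scale-invariant to <2% and equals `b/a` for an ellipse with semi-axes
`a ≥ b`.

## Centrosome distance and F-actin profiles

The centrosome-to-synapse distance is the 2D in-plane Euclidean distance
between two annotated points (the pericentrin punctum and the synapse
center), in µm; the measurement mirrors a manual two-point distance, not
a point-to-membrane-curve distance, and no 3D (through-stack) component
is included. Bins: ≤1 µm, (1, 3] µm, >3 µm — both boundaries close the
left bin, so 1.0 µm counts as polarised and 3.0 µm as intermediate.
`detect_punctum` optionally automates the punctum annotation as the
maximum of the 2-px-Gaussian-smoothed channel inside the mask
(lexicographic tie-break, with a warning).

F-actin profiles sample bilinear-interpolated intensity at 0.5-px steps
along full-width lines through the hull centroid at a configurable set
of angles (default 0/45/90/135°), with positions reported as signed µm
from the center. Peak finding uses a prominence threshold of 10% of the
profile's dynamic range; classification of ring-vs-filled patterns is
left to the user.

## Statistics

`compare_groups` implements two-sided tests on per-cell values:
Student's pooled-variance t (the conventional independent-samples
default; Welch's form via `welch=True` since equal variances are rarely
guaranteed) and Mann–Whitney U (exact null when min(n) ≤ 8 and the data
are tie-free, otherwise the tie-corrected normal approximation). Fully
degenerate inputs (zero variance everywhere) return p = 1 rather than
NaN. No multiple-testing correction is applied by default — the
intended use is small discovery-phase panels — but Benjamini–Hochberg
adjustment is available. `batch_report` compares every metric of a
long-format table between exactly two groups and can emit box-whisker
plots (Tukey 1.5×IQR whiskers for per-cell metrics, min–max whiskers
for per-subject summaries).

## Synthetic data: what it emulates and what it does not

`make_filament_cell` renders straight, anti-aliased filaments inside an
elliptical footprint (optionally perturbed by `1 + ε·cos(mθ)` on the
boundary radius): each filament is radial (organising center → boundary)
with probability `radiality_alpha` and otherwise a short tangential
chord (≤15 px, perpendicular to the local radius at its anchor point),
over a diffuse cytoplasmic level, plus additive Gaussian noise clipped
at 0. Straight segments are deliberate: they give an exact analytic
ground-truth orientation per drawn pixel, which curved filaments would
destroy. Defaults emulate a spread CTL at 63×/1.4 NA confocal sampling:
0.1 µm/px, semi-axes (42, 34) px ≈ 8.4 × 6.8 µm, 60 filaments,
organising center (3, 4) px ≈ 0.5 µm off-center, intensity levels
background 5 / cytoplasm 120 / filament 220, noise σ = 5. All
randomness flows through one `numpy` generator seeded per call.

`make_conjugate_image` adds the conjugate-stage channels: a uniform
CD8 cell body, an F-actin ring (boundary band, 3-px erosion) over a
dimmer interior, and a single Gaussian pericentrin punctum (sd 2 px).

Not emulated: PSF convolution and other photophysics (bleaching,
Poisson shot noise), filament curvature and crossing-density effects,
3D structure, touching cells, uneven illumination. Passing tests on
this generator therefore demonstrate the correctness of the
*measurements* given images with the assumed structure, not robustness
to every artefact of real confocal data.

Large simulation cohorts (the statistical calibration below) use a
scaled-down cell — semi-axes (24, 20) px, 24 filaments on a 64×64
raster (`SMALL_CELL`) — chosen so thousands of full pipeline runs stay
cheap while each cell still yields ~850 pixels in section 2.

## Calibration results the package computes for itself

`synapsekit.calibration` simulates complete experiments: a mean-DoR
sweep across radiality levels {0, 0.25, 0.5, 0.75, 1} (30 cells/level)
that must be strictly increasing; the t-test's type-I error with both
cohorts at radiality 0.6 (30 cells/group, 200 replicates), expected at
the nominal 5%; and its power for radiality 1.0 vs 0.2 at n = 30/group
(100 replicates). These are recomputed — never stored — by the test
suite and by `scripts/acceptance.py`.
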