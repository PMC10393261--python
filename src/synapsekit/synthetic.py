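"""Synthetic fluorescence images with known ground truth.

Real confocal data for this assay are not publicly deposited, so every
downstream stage is validated on simulated cells that reproduce the
structures the measurements target:

* a roughly elliptical cell footprint with controllable boundary
  irregularity (a cosine perturbation of the boundary radius);
* a microtubule-like network of straight anti-aliased filaments emanating
  from an off-center organising point — radial or tangential per
  filament, mixed by ``radiality_alpha`` (1 = purely radial, 0 = purely
  tangential);
* a diffuse cytoplasmic background below the filament intensity, plus
  additive Gaussian noise;
* conjugate-style channels: a cell-shaped CD8 channel, an F-actin ring at
  the mask boundary, and a single Gaussian centrosome punctum.

Filaments are straight segments rather than curved splines: straightness
gives an exact analytic ground-truth orientation at every drawn pixel,
which curved filaments would destroy.  Tangential filaments are short
chords (length <= 15 px) perpendicular to the local radius so their axial
direction stays well defined.  All randomness flows through one seeded
generator per call; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.draw import line_aa
from skimage.morphology import disk

from .io import ChannelImage

__all__ = [
    "SyntheticCellSpec",
    "GroundTruth",
    "make_rough_mask",
    "make_filament_cell",
    "make_conjugate_image",
    "dor_cohort",
    "SMALL_CELL",
]


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one simulated cell.

    Defaults emulate an in-vitro-spread CTL imaged at 63x/1.4 NA confocal
    sampling (0.1 um/px): an 8.4 x 6.8 um elliptical footprint, ~60
    microtubule filaments, an organising center ~0.5 um off the footprint
    center, and mild Gaussian readout noise on a 0-255-like intensity
    scale (background 5, cytoplasm 120, filament 220).
    """

    semi_axes: tuple[float, float] = (42.0, 34.0)  # (row, col) semi-axes, px
    boundary_epsilon: float = 0.0  # relative boundary-perturbation amplitude
    boundary_lobes: int = 0
    radiality_alpha: float = 1.0
    n_filaments: int = 60
    organizing_center_offset: tuple[float, float] = (3.0, 4.0)
    noise_sigma: float = 5.0
    seed: int = 0
    pixel_size_um: float = 0.1
    background: float = 5.0
    cytoplasm: float = 120.0
    filament: float = 220.0
    tangential_length_px: float = 15.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) < 4:
            raise ValueError(f"degenerate footprint: semi-axes {self.semi_axes} < 4 px")
        if not (0.0 <= self.radiality_alpha <= 1.0):
            raise ValueError("radiality_alpha must be in [0, 1]")
        if not (0.0 <= self.boundary_epsilon < 1.0):
            raise ValueError("boundary_epsilon must be in [0, 1)")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (self.background < self.filament):
            raise ValueError("background intensity must be below filament intensity")


# Scaled-down cell used for large simulation cohorts (64x64 raster).
SMALL_CELL = SyntheticCellSpec(
    semi_axes=(24.0, 20.0),
    n_filaments=24,
    organizing_center_offset=(2.0, 2.0),
)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, for validating measurements."""

    mask: np.ndarray
    orientation: np.ndarray  # axial angle [0, pi) where drawn, nan elsewhere
    centrosome: tuple[float, float]
    drawn_pixels: np.ndarray
    synapse_center: tuple[float, float] | None = None


def _boundary_radius(phi: np.ndarray, semi_axes: tuple[float, float],
                     eps: float, m: int, phase: float) -> np.ndarray:
    a_r, a_c = semi_axes
    base = 1.0 / np.sqrt((np.sin(phi) / a_r) ** 2 + (np.cos(phi) / a_c) ** 2)
    return base * (1.0 + eps * np.cos(m * phi + phase))


def _fill_mask(shape: tuple[int, int], center: tuple[float, float],
               semi_axes: tuple[float, float], eps: float, m: int,
               phase: float) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    rho = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)
    return rho <= _boundary_radius(phi, semi_axes, eps, m, phase)


def make_rough_mask(
    semi_axes: tuple[float, float],
    eps: float = 0.0,
    m: int = 0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Filled region with boundary radius ``r(theta) * (1 + eps*cos(m*theta))``.

    ``eps = 0`` gives the exact digitised ellipse (a disk for equal
    semi-axes).  The cosine perturbation is deterministic; ``seed`` only
    randomises its angular phase.  ``eps >= 1`` would let the radius reach
    zero and is rejected.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps >= 1:
        raise ValueError(f"eps must be < 1 to keep the mask simply connected, got {eps}")
    if min(semi_axes) < 4:
        raise ValueError(f"degenerate footprint: semi-axes {semi_axes} < 4 px")
    if shape is None:
        ext = int(np.ceil(2 * max(semi_axes) * (1 + eps))) + 8
        shape = (ext, ext)
    phase = float(np.random.default_rng(seed).uniform(0, 2 * np.pi)) if m > 0 else 0.0
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return _fill_mask(shape, center, semi_axes, eps, m, phase)


def _ray_extent(mask: np.ndarray, origin: tuple[float, float],
                direction: tuple[float, float], step: float = 0.5) -> float:
    """Distance from ``origin`` to the mask boundary along ``direction``."""
    rows, cols = mask.shape
    r_max = float(np.hypot(rows, cols))
    n = int(r_max / step) + 1
    rho = np.arange(n) * step
    pr = np.clip(np.round(origin[0] + rho * direction[0]).astype(int), 0, rows - 1)
    pc = np.clip(np.round(origin[1] + rho * direction[1]).astype(int), 0, cols - 1)
    inside = mask[pr, pc]
    if not inside[0]:
        return 0.0
    out = np.flatnonzero(~inside)
    return rho[out[0] - 1] if out.size else rho[-1]


def _draw_segment(img: np.ndarray, orientation: np.ndarray, drawn: np.ndarray,
                  mask: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
                  lo: float, hi: float) -> None:
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    if (r0, c0) == (r1, c1):
        return
    rr, cc, val = line_aa(r0, c0, r1, c1)
    ok = (
        (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    )
    rr, cc, val = rr[ok], cc[ok], val[ok]
    ok = mask[rr, cc]
    rr, cc, val = rr[ok], cc[ok], val[ok]
    if rr.size == 0:
        return
    img[rr, cc] = np.maximum(img[rr, cc], lo + (hi - lo) * val)
    core = val >= 0.5
    angle = np.mod(np.arctan2(r1 - r0, c1 - c0), np.pi)
    orientation[rr[core], cc[core]] = angle
    drawn[rr[core], cc[core]] = True


def make_filament_cell(spec: SyntheticCellSpec) -> tuple[ChannelImage, GroundTruth]:
    """Render one tubulin-like cell image and its ground truth.

    Each filament is radial with probability ``radiality_alpha`` (a
    segment from the organising center to the footprint boundary) and
    otherwise tangential (a short chord perpendicular to the local
    radius).  Ground truth records the footprint mask, the axial angle of
    the drawn segment at every core filament pixel, and the organising
    center as the centrosome position.
    """
    rng = np.random.default_rng(spec.seed)
    eps, m = spec.boundary_epsilon, spec.boundary_lobes
    ext = int(np.ceil(2 * max(spec.semi_axes) * (1 + eps))) + 12
    shape = (ext, ext)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    phase = float(rng.uniform(0, 2 * np.pi)) if m > 0 else 0.0
    mask = _fill_mask(shape, center, spec.semi_axes, eps, m, phase)

    oc = (center[0] + spec.organizing_center_offset[0],
          center[1] + spec.organizing_center_offset[1])
    if not mask[int(round(oc[0])), int(round(oc[1]))]:
        raise ValueError("organizing center lies outside the footprint")

    img = np.where(mask, spec.cytoplasm, spec.background).astype(float)
    orientation = np.full(shape, np.nan)
    drawn = np.zeros(shape, dtype=bool)

    mask_rows, mask_cols = np.nonzero(mask)
    for _ in range(spec.n_filaments):
        if rng.random() < spec.radiality_alpha:
            theta = rng.uniform(0, 2 * np.pi)
            u = (np.sin(theta), np.cos(theta))
            reach = _ray_extent(mask, oc, u)
            if reach < 3:
                continue
            p0 = (oc[0] + 2 * u[0], oc[1] + 2 * u[1])
            p1 = (oc[0] + reach * u[0], oc[1] + reach * u[1])
        else:
            j = rng.integers(mask_rows.size)
            p = (float(mask_rows[j]), float(mask_cols[j]))
            dr, dc = p[0] - oc[0], p[1] - oc[1]
            norm = float(np.hypot(dr, dc))
            if norm < 2:
                continue
            # chord perpendicular to the local radius from the organising center
            u = (dc / norm, -dr / norm)
            half = spec.tangential_length_px / 2.0
            e0 = min(half, _ray_extent(mask, p, (-u[0], -u[1])))
            e1 = min(half, _ray_extent(mask, p, u))
            if e0 + e1 < 3:
                continue
            p0 = (p[0] - e0 * u[0], p[1] - e0 * u[1])
            p1 = (p[0] + e1 * u[0], p[1] + e1 * u[1])
        _draw_segment(img, orientation, drawn, mask, p0, p1,
                      spec.cytoplasm, spec.filament)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, None)
    image = ChannelImage(img, spec.pixel_size_um, "tubulin")
    truth = GroundTruth(mask=mask, orientation=orientation, centrosome=oc,
                        drawn_pixels=drawn)
    return image, truth


def make_conjugate_image(
    centrosome_offset_px: tuple[float, float],
    synapse_center_px: tuple[float, float] | None,
    spec: SyntheticCellSpec,
) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Render CD8 / F-actin / pericentrin channels of one conjugate.

    The synapse center defaults to the footprint center; the centrosome
    sits at ``synapse_center + centrosome_offset_px``.  The F-actin
    channel carries a bright ring at the mask boundary with a dimmer
    interior; the pericentrin channel contains a single Gaussian punctum
    (sd 2 px) at the centrosome.  Both points must lie inside the
    footprint.
    """
    rng = np.random.default_rng(spec.seed)
    eps, m = spec.boundary_epsilon, spec.boundary_lobes
    ext = int(np.ceil(2 * max(spec.semi_axes) * (1 + eps))) + 12
    shape = (ext, ext)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    phase = float(rng.uniform(0, 2 * np.pi)) if m > 0 else 0.0
    mask = _fill_mask(shape, center, spec.semi_axes, eps, m, phase)

    if synapse_center_px is None:
        synapse_center_px = center
    syn = (float(synapse_center_px[0]), float(synapse_center_px[1]))
    cen = (syn[0] + centrosome_offset_px[0], syn[1] + centrosome_offset_px[1])
    for name, (r, c) in (("synapse center", syn), ("centrosome", cen)):
        if not (0 <= int(round(r)) < shape[0] and 0 <= int(round(c)) < shape[1]) \
                or not mask[int(round(r)), int(round(c))]:
            raise ValueError(f"{name} {r, c} lies outside the footprint")

    cd8 = np.where(mask, 150.0, spec.background)

    ring = mask & ~binary_erosion(mask, structure=disk(3))
    actin = np.where(mask, 30.0, spec.background)
    actin[ring] = 200.0

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    punctum = 250.0 * np.exp(-((rr - cen[0]) ** 2 + (cc - cen[1]) ** 2) / (2 * 2.0**2))
    pericentrin = spec.background + punctum

    channels = {}
    for name, plane in (("cd8", cd8), ("actin", actin), ("pericentrin", pericentrin)):
        if spec.noise_sigma > 0:
            plane = plane + rng.normal(0.0, spec.noise_sigma, size=shape)
        channels[name] = ChannelImage(np.clip(plane, 0.0, None),
                                      spec.pixel_size_um, name)
    truth = GroundTruth(mask=mask, orientation=np.full(shape, np.nan),
                        centrosome=cen, drawn_pixels=np.zeros(shape, dtype=bool),
                        synapse_center=syn)
    return channels, truth


def dor_cohort(
    alpha: float,
    n_cells: int,
    seed: int,
    base_spec: SyntheticCellSpec = SMALL_CELL,
    relative_distance: float = 2.0,
    K: int = 4,
    **dor_kwargs,
) -> np.ndarray:
    """Per-cell DoR values for a cohort simulated at one radiality level.

    Runs the full measurement pipeline (segmentation, structure tensor,
    EFD sections, DoR) on ``n_cells`` independent cells and returns the
    DoR at the requested relative radial distance for each.  Used for
    power/calibration studies of the group comparisons.
    """
    from .radiality import dor_at, dor_profile  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    out = np.empty(n_cells)
    for i in range(n_cells):
        spec = replace(base_spec, radiality_alpha=alpha,
                       seed=int(rng.integers(2**31 - 1)))
        image, _ = make_filament_cell(spec)
        profile = dor_profile(image, K=K, cell_id=f"alpha{alpha}_{i}", **dor_kwargs)
        out[i] = dor_at(profile, relative_distance)
    return out
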