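"""Single-cell segmentation and the radial/circular reference fields.

A cell mask is obtained by global Otsu thresholding of the raw raster,
removal of small connected components, and — if several components
survive — keeping the largest.  The cell "center" used by every radial
measurement is the centroid of the filled convex hull of the mask, which
is robust to protrusions and intensity asymmetries of the cell body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image

from .io import ChannelImage

__all__ = ["CellMask", "segment_cell", "mask_to_cell", "radial_circular_fields"]


@dataclass(frozen=True)
class CellMask:
    """Binary footprint of one cell with its convex hull and hull centroid.

    ``center_of_mass`` is the centroid of the filled hull region in
    ``(row, col)`` coordinates.
    """

    mask: np.ndarray
    hull: np.ndarray
    center_of_mass: tuple[float, float]
    area_px: int

    def __post_init__(self) -> None:
        if self.mask.shape != self.hull.shape:
            raise ValueError("mask and hull shapes differ")
        r, c = self.center_of_mass
        if not self.hull[int(round(r)), int(round(c))]:
            raise ValueError("center_of_mass does not lie inside the hull")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def mask_to_cell(mask: np.ndarray) -> CellMask:
    """Build a :class:`CellMask` (hull, hull centroid, area) from a binary raster."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    hull = convex_hull_image(mask)
    rr, cc = np.nonzero(hull)
    center = (float(rr.mean()), float(cc.mean()))
    return CellMask(mask=mask, hull=hull, center_of_mass=center,
                    area_px=int(mask.sum()))


def segment_cell(image: ChannelImage, min_area_px: int = 100) -> CellMask:
    """Segment the single cell in ``image`` by Otsu thresholding.

    Components (8-connected) smaller than ``min_area_px`` are discarded;
    if several remain, the largest is kept.  Raises ``ValueError`` on a
    constant image (Otsu undefined) or when no component reaches
    ``min_area_px``.
    """
    px = image.pixels
    if np.unique(px).size < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    thresh = threshold_otsu(px)
    fg = px > thresh
    lab = label(fg, connectivity=2)
    if lab.max() == 0:
        raise ValueError("no cell found: no foreground after thresholding")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    big = np.flatnonzero(sizes >= min_area_px)
    if big.size == 0:
        raise ValueError(
            f"no cell found: largest component {sizes.max()} px < min_area_px={min_area_px}"
        )
    keep = big[np.argmax(sizes[big])]
    return mask_to_cell(lab == keep)


def radial_circular_fields(
    cell: CellMask, r_min_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unit radial and circular vector fields about the hull centroid.

    Returns two ``(rows, cols, 2)`` arrays of ``(d_row, d_col)`` unit
    vectors.  At each hull pixel farther than ``r_min_px`` from the
    center, ``radial`` points away from the center and ``circular`` is
    ``radial`` rotated +90° (counter-clockwise in row-down coordinates:
    ``(dr, dc) -> (dc, -dr)``).  Pixels outside the hull or within
    ``r_min_px`` of the center are NaN.  The rotation sign is a fixed
    convention; the radiality statistic uses absolute dot products, so it
    cannot affect any result.
    """
    rows, cols = cell.shape
    r0, c0 = cell.center_of_mass
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dr = rr - r0
    dc = cc - c0
    dist = np.hypot(dr, dc)
    valid = cell.hull & (dist > r_min_px)

    radial = np.full((rows, cols, 2), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial[..., 0] = np.where(valid, dr / dist, np.nan)
        radial[..., 1] = np.where(valid, dc / dist, np.nan)
    circular = np.stack([radial[..., 1], -radial[..., 0]], axis=-1)
    return radial, circular
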