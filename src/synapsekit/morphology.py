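"""Per-cell shape metrics: roughness, roundness and their ingredients.

Two complementary morphometrics describe how far a T-cell footprint
deviates from a smooth round synapse:

* roughness = P / P_hull — Crofton perimeter of the mask over the Crofton
  perimeter of its convex hull; 1 for convex shapes, larger for
  protrusive, irregular boundaries (small-scale irregularity).
* roundness = 4 * area / (pi * MA^2) — with MA the major-axis length of
  the ellipse with the same normalised second central moments as the
  mask; 1 for a circle, smaller for elongated shapes (large-scale
  deviation from round).

Both perimeters use the same 4-direction Crofton estimator so the ratio's
discretisation bias largely cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, perimeter_crofton, regionprops
from skimage.morphology import convex_hull_image

from .segmentation import CellMask

__all__ = ["MorphologyMetrics", "crofton_perimeter", "major_axis", "shape_metrics"]


@dataclass(frozen=True)
class MorphologyMetrics:
    cell_id: str
    area_px: int
    perimeter_crofton_px: float
    hull_perimeter_crofton_px: float
    major_axis_px: float
    roughness: float
    roundness: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def crofton_perimeter(mask: np.ndarray) -> float:
    """Boundary length (px) of a binary mask by the 4-direction Crofton method."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(perimeter_crofton(mask, directions=4))


def _single_region(mask: np.ndarray):
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    props = regionprops(lab)
    if not props:
        raise ValueError("empty mask")
    return max(props, key=lambda p: p.area)


def major_axis(mask: np.ndarray) -> float:
    """Major-axis length of the moment-equivalent ellipse of the mask.

    MA = 4 * sqrt(largest eigenvalue of the normalised second central
    moment matrix of the mask's pixel coordinates).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise ValueError(f"mask area {mask.sum()} < 4: moments degenerate")
    region = _single_region(mask)
    ma = float(region.axis_major_length)
    if not np.isfinite(ma) or ma <= 0:
        raise ValueError("degenerate (collinear) mask: major axis undefined")
    return ma


def shape_metrics(cell: CellMask, cell_id: str = "cell") -> MorphologyMetrics:
    """Assemble all shape metrics for one cell mask."""
    mask = cell.mask
    hull = cell.hull if cell.hull.any() else convex_hull_image(mask)
    p = crofton_perimeter(mask)
    p_hull = crofton_perimeter(hull)
    ma = major_axis(mask)
    area = int(mask.sum())
    return MorphologyMetrics(
        cell_id=cell_id,
        area_px=area,
        perimeter_crofton_px=p,
        hull_perimeter_crofton_px=p_hull,
        major_axis_px=ma,
        roughness=p / p_hull,
        roundness=4.0 * area / (np.pi * ma**2),
    )
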