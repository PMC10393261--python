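"""Raster image and annotation I/O.

All images are handled as plain 2D float arrays with an attached physical
pixel size in micrometres.  The coordinate convention throughout the
package is 0-based ``(row, col)`` with the row axis pointing down; physical
distances are pixel displacements multiplied by ``pixel_size_um``.

Intensities are never rescaled on load: downstream thresholding (Otsu) and
the structure tensor are tolerant to the intensity scale, and silent
normalisation would change thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelImage",
    "ImageStack",
    "PointAnnotation",
    "read_image",
    "write_image",
    "read_stack",
    "max_project",
    "read_annotations",
    "write_annotations",
    "load_config",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel 2D fluorescence image plane.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities (any positive scale).
    pixel_size_um
        Physical edge length of one pixel in micrometres, > 0.
    channel_name
        Free-text stain label (e.g. ``"tubulin"``, ``"CD8"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(
                f"image must be 2D with at least 8x8 pixels, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0:
            raise ValueError("image contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImageStack:
    """An ordered z-stack of identically shaped 2D planes."""

    slices: np.ndarray  # (n_slices, rows, cols)
    z_step_um: float
    pixel_size_um: float = 1.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError(
                f"stack must be a (n, rows, cols) array with n >= 1, got {arr.shape}"
            )
        if not (self.z_step_um > 0):
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        object.__setattr__(self, "slices", arr)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class PointAnnotation:
    """A manually (or automatically) marked point on one image."""

    image_id: str
    role: str  # "centrosome" or "synapse_center"
    row: float
    col: float

    _ROLES = ("centrosome", "synapse_center")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if self.row < 0 or self.col < 0:
            raise ValueError("annotation coordinates must be >= 0")


def read_image(path: str | Path, pixel_size_um: float, channel_name: str = "") -> ChannelImage:
    """Read a single-plane grayscale TIFF.

    Integer pixel types are converted to float without rescaling.  A file
    holding more than one plane is rejected; use :func:`read_stack`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(
            f"{path} holds a {arr.ndim}D array; expected a single 2D plane "
            "(use read_stack for z-stacks)"
        )
    return ChannelImage(arr.astype(float), pixel_size_um, channel_name)


def write_image(path: str | Path, image: ChannelImage | np.ndarray, dtype=None) -> None:
    """Write a 2D raster to TIFF. Values are cast to ``dtype`` if given."""
    arr = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    if dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def read_stack(path: str | Path, pixel_size_um: float, z_step_um: float,
               channel_name: str = "") -> ImageStack:
    """Read a multi-plane grayscale TIFF as a z-stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.squeeze(np.asarray(tifffile.imread(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path} holds a {arr.ndim}D array; expected a z-stack")
    return ImageStack(arr.astype(float), z_step_um, pixel_size_um, channel_name)


def max_project(stack: ImageStack, slice_range: tuple[int, int] | None = None) -> ChannelImage:
    """Maximum-intensity projection over an inclusive slice range.

    The original analyses run on maximum projections of a few optical
    sections at the cell–coverslip contact; which sections to project is
    left to the caller via ``slice_range`` (default: all slices).
    """
    n = stack.n_slices
    if slice_range is None:
        slice_range = (0, n - 1)
    first, last = slice_range
    if not (0 <= first <= last <= n - 1):
        raise IndexError(
            f"slice_range {slice_range} invalid for stack of {n} slices"
        )
    proj = stack.slices[first : last + 1].max(axis=0)
    return ChannelImage(proj, stack.pixel_size_um, stack.channel_name)


# -- annotation tables -------------------------------------------------------

_ANNOT_COLS = ["image_id", "role", "row", "col"]


def read_annotations(path: str | Path) -> list[PointAnnotation]:
    """Read a point-annotation CSV with header image_id,role,row,col."""
    df = pd.read_csv(path)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns {missing}")
    return [
        PointAnnotation(str(r.image_id), str(r.role), float(r.row), float(r.col))
        for r in df.itertuples()
    ]


def write_annotations(path: str | Path, annotations: list[PointAnnotation]) -> None:
    pd.DataFrame(
        [(a.image_id, a.role, a.row, a.col) for a in annotations],
        columns=_ANNOT_COLS,
    ).to_csv(path, index=False)


# -- run configuration -------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "pixel_size_um": 0.1,
    "channel_order": ["tubulin", "actin", "cd8", "pericentrin"],
    "segmentation": {"min_area_px": 100},
    "radiality": {
        "sigma_px": 1.5,
        "coherence_min": 0.0,
        "n_harmonics": 10,
        "n_sections": 4,
    },
    "synapse": {"angles_deg": [0.0, 45.0, 90.0, 135.0]},
    "stats": {"test": "t_independent", "welch": False, "fdr": False},
}


def _deep_update(base: dict, other: dict) -> dict:
    out = dict(base)
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration, falling back to package defaults.

    Keys absent from the file keep their defaults; CLI flags override the
    file (handled in :mod:`synapsekit.cli`).
    """
    if path is None:
        return {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return _deep_update(DEFAULT_CONFIG, user)
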