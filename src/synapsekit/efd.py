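"""Elliptical Fourier descriptors (EFD) for closed contours.

A closed contour is represented as a truncated Fourier series of its
arc-length parametrisation (Kuhl & Giardina's chain-code formulation,
applied here to polygonal contours): harmonic ``n`` contributes

    row(t) += a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    col(t) += c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

about the locus ``(A0, C0)``.  The first harmonic is the best-fitting
ellipse; higher harmonics add boundary detail.  Convex hull contours in
this package are smooth and star-shaped, so ten harmonics reconstruct
them to sub-pixel accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

__all__ = ["EFDContour", "fit_efd", "fit_hull_efd", "evaluate_contour"]


@dataclass(frozen=True)
class EFDContour:
    """Truncated elliptical Fourier series of one closed contour.

    ``coefficients`` has shape ``(n_harmonics, 4)`` with columns
    ``(a_n, b_n, c_n, d_n)``: ``(a, b)`` drive the row coordinate and
    ``(c, d)`` the column coordinate.  ``locus`` is the series' constant
    term in ``(row, col)``.  ``scale_fraction`` is 1 for the outer hull
    contour and ``k/K`` for intermediate contours scaled toward the
    center.  ``raster_shape`` records the source image shape so section
    maps can be rasterised without re-passing it.
    """

    coefficients: np.ndarray
    locus: tuple[float, float]
    scale_fraction: float = 1.0
    raster_shape: tuple[int, int] | None = None

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.shape[0]

    def first_harmonic_semi_axes(self) -> tuple[float, float]:
        """Semi-axes (major, minor) of the first-harmonic ellipse."""
        m = self.coefficients[0].reshape(2, 2)
        s = np.linalg.svd(m, compute_uv=False)
        return float(s[0]), float(s[1])


def fit_efd(contour: np.ndarray, n_harmonics: int = 10) -> EFDContour:
    """Fit an elliptical Fourier series to a closed polygonal contour.

    Parameters
    ----------
    contour
        ``(N, 2)`` array of ``(row, col)`` vertices.  The polygon is
        treated as closed; a repeated last point is tolerated.
    n_harmonics
        Series order; the contour must supply at least ``3 * n_harmonics``
        sample points.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < max(3, 3 * n_harmonics):
        raise ValueError(
            f"contour has {pts.shape[0]} points; need >= {3 * n_harmonics} "
            f"for {n_harmonics} harmonics"
        )
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        d, dt = d[keep], dt[keep]
    if dt.size < 3:
        raise ValueError("degenerate contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("degenerate contour with zero length")
    phi = 2.0 * np.pi * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    cosn = np.cos(n * phi)  # (H, N+1)
    sinn = np.sin(n * phi)
    dcos = cosn[:, 1:] - cosn[:, :-1]
    dsin = sinn[:, 1:] - sinn[:, :-1]
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)  # (H,)

    slopes = d / dt[:, None]  # (N, 2)
    a = const * (dcos @ slopes[:, 0])
    b = const * (dsin @ slopes[:, 0])
    c = const * (dcos @ slopes[:, 1])
    e = const * (dsin @ slopes[:, 1])
    coeffs = np.stack([a, b, c, e], axis=1)

    # DC component (series locus)
    t0, t1 = t[:-1], t[1:]
    xi = np.cumsum(d[:, 0]) - slopes[:, 0] * t1
    zeta = np.cumsum(d[:, 1]) - slopes[:, 1] * t1
    A0 = closed[0, 0] + np.sum(slopes[:, 0] / 2 * (t1**2 - t0**2) + xi * (t1 - t0)) / T
    C0 = closed[0, 1] + np.sum(slopes[:, 1] / 2 * (t1**2 - t0**2) + zeta * (t1 - t0)) / T

    return EFDContour(coeffs, (float(A0), float(C0)))


def evaluate_contour(
    efd: EFDContour,
    n_points: int = 512,
    scale: float = 1.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Sample ``n_points`` ``(row, col)`` points along the contour.

    With ``scale != 1`` the curve is shrunk/expanded about ``center``
    (default: the series locus), which is how intermediate contours
    between the hull edge and the cell center are produced.
    """
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    H = efd.n_harmonics
    n = np.arange(1, H + 1)[:, None]
    cosn = np.cos(2 * np.pi * n * t)
    sinn = np.sin(2 * np.pi * n * t)
    rows = efd.locus[0] + efd.coefficients[:, 0] @ cosn + efd.coefficients[:, 1] @ sinn
    cols = efd.locus[1] + efd.coefficients[:, 2] @ cosn + efd.coefficients[:, 3] @ sinn
    pts = np.stack([rows, cols], axis=1)
    if scale != 1.0:
        c = np.asarray(center if center is not None else efd.locus, dtype=float)
        pts = c + scale * (pts - c)
    return pts


def fit_hull_efd(cell, n_harmonics: int = 10) -> EFDContour:
    """Fit an EFD to the boundary of a cell's convex hull.

    ``cell`` is a :class:`~synapsekit.segmentation.CellMask`.  Raises
    ``ValueError`` for degenerate (near-collinear) hulls or when the
    boundary is too short for the requested order.
    """
    hull = cell.hull
    if hull.sum() < 9:
        raise ValueError("degenerate hull: too few pixels for a contour fit")
    contours = find_contours(hull.astype(float), 0.5)
    if not contours:
        raise ValueError("degenerate hull: no boundary contour found")
    boundary = max(contours, key=len)
    efd = fit_efd(boundary, n_harmonics=n_harmonics)
    return EFDContour(
        efd.coefficients, efd.locus, scale_fraction=1.0, raster_shape=hull.shape
    )
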