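"""Contour validity metrics: Dice area overlap and Hausdorff boundary distance.

The Dice metric DM = 2|A∩B| / (|A|+|B|) is computed on rasterized areas, and
the Hausdorff distance

    HD = max( max_x min_y d(x, y), max_y min_x d(x, y) )

on densely resampled contour polylines in physical millimetres — two distinct
definitions for two distinct questions (area overlap vs worst-case boundary
deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .io_formats import Contour, ContourSet

__all__ = [
    "RegionMask",
    "ContourPointSet",
    "rasterize",
    "dice",
    "hausdorff",
    "contour_dice",
    "contour_hausdorff",
    "pairwise_metrics",
]

DEFAULT_RESAMPLE_STEP_MM = 0.25


@dataclass(frozen=True)
class RegionMask:
    """Boolean pixel mask of a contour's interior on the image grid."""

    mask: np.ndarray  # (rows, cols) bool
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2D, got {m.ndim}D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ContourPointSet:
    """Densely resampled contour points in physical mm coordinates."""

    points_mm: np.ndarray  # (n, 2)
    step_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points_mm must be a non-empty (n, 2) array")
        object.__setattr__(self, "points_mm", pts)


def rasterize(
    contour: Contour,
    grid_shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> RegionMask:
    """Pixel-center rasterization: a pixel is included iff its center lies
    strictly inside the polygon (points on an edge are excluded)."""
    rows, cols = grid_shape
    pts = contour.points
    if (
        pts[:, 0].min() < -0.5
        or pts[:, 1].min() < -0.5
        or pts[:, 0].max() > cols - 0.5
        or pts[:, 1].max() > rows - 0.5
    ):
        raise ValueError("contour extends outside the pixel grid")
    poly = contour.polygon()
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(rows, cols)
    return RegionMask(mask=inside, pixel_spacing_mm=pixel_spacing_mm)


def dice(a: RegionMask, b: RegionMask) -> float:
    """2·|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"mask shapes differ: {a.mask.shape} vs {b.mask.shape}")
    na, nb = int(a.mask.sum()), int(b.mask.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a.mask, b.mask).sum()) / (na + nb)


def resample_contour_mm(
    contour: Contour,
    pixel_spacing_mm: tuple[float, float],
    step_mm: float = DEFAULT_RESAMPLE_STEP_MM,
) -> ContourPointSet:
    """Resample the closed polyline at an arc-length step ≤ ``step_mm`` in mm."""
    row_mm, col_mm = pixel_spacing_mm
    pts = contour.points * np.array([col_mm, row_mm])  # (x, y) -> mm
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total == 0:
        return ContourPointSet(points_mm=pts[:1], step_mm=step_mm)
    n = max(int(np.ceil(total / step_mm)), len(pts))
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, arclen, closed[:, 0])
    y = np.interp(t, arclen, closed[:, 1])
    return ContourPointSet(points_mm=np.column_stack([x, y]), step_mm=step_mm)


def hausdorff(x: ContourPointSet, y: ContourPointSet) -> float:
    """Symmetric Hausdorff distance in mm over the resampled point sets."""
    tx, ty = cKDTree(x.points_mm), cKDTree(y.points_mm)
    d_xy = ty.query(x.points_mm)[0].max()
    d_yx = tx.query(y.points_mm)[0].max()
    return float(max(d_xy, d_yx))


def contour_dice(
    a: Contour,
    b: Contour,
    grid_shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> float:
    return dice(
        rasterize(a, grid_shape, pixel_spacing_mm),
        rasterize(b, grid_shape, pixel_spacing_mm),
    )


def contour_hausdorff(
    a: Contour,
    b: Contour,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    step_mm: float = DEFAULT_RESAMPLE_STEP_MM,
) -> float:
    return hausdorff(
        resample_contour_mm(a, pixel_spacing_mm, step_mm),
        resample_contour_mm(b, pixel_spacing_mm, step_mm),
    )


def pairwise_metrics(
    set_a: ContourSet,
    set_b: ContourSet,
    grid_shape: tuple[int, int],
    structure: str = "rv_endo",
) -> list[dict]:
    """Per-slice Dice and Hausdorff for every (phase, slice) present in both sets.

    Rows are suitable for pooling across slices and subjects before taking
    medians/IQRs.
    """
    spacing = set_a.pixel_spacing_mm
    rows = []
    for ca in set_a.contours:
        if ca.structure != structure:
            continue
        cb = set_b.get(ca.phase, ca.slice, structure)
        if cb is None:
            continue
        rows.append(
            {
                "phase": ca.phase,
                "slice": ca.slice,
                "dice": contour_dice(ca, cb, grid_shape, spacing),
                "hausdorff_mm": contour_hausdorff(ca, cb, spacing),
            }
        )
    return rows
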