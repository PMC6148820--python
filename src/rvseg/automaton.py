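"""Seeded cellular-automaton label evolution on a single slice.

Each pixel carries a label (unlabeled / foreground / background), a strength
θ ∈ [0, 1] (seeds start at 1, unlabeled pixels at 0) and a feature value (the
slice intensity min–max normalized to [0, 1]).  At every synchronous
iteration a pixel q attacks each neighbor p with strength

    attack = λ · g(|I_p − I_q|) · θ_q,        g(d) = 1 − d,

and p is conquered iff the attack strictly exceeds θ_p, whereupon p adopts
q's label and the attack strength.  Among simultaneous attackers the maximum
strength wins; exact ties are broken by a fixed neighbor scan order
(N, NE, E, SE, S, SW, W, NW).  Updates are Jacobi-style (all attacks are
computed against the previous iteration's state), so the result is
independent of memory layout.  Because every conquest strictly increases θ
and θ ≤ 1 on a finite grid, the iteration reaches a fixpoint.

Foreground seeds come from the user's rough endocardial contour (eroded by a
safety margin); background seeds are the image border plus far-away pixels
whose intensity barely changes over the cardiac cycle — static tissue
identified from the temporal standard-deviation map.

λ ∈ (0, 1] attenuates the transmitted strength per step and thereby encodes
the distance to the seeds; at the default λ = 1 distance still matters
because noise makes g < 1 along any path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk

from .contour_metrics import rasterize
from .io_formats import CineStack, Contour

__all__ = [
    "UNLABELED",
    "FOREGROUND",
    "BACKGROUND",
    "LabelField",
    "AutomatonConfig",
    "init_labels",
    "evolve",
    "extract_contour",
    "optimize_seed",
]

UNLABELED, FOREGROUND, BACKGROUND = 0, 1, 2

# neighbor scan order: N, NE, E, SE, S, SW, W, NW as (drow, dcol)
_NEIGHBORS_8 = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_NEIGHBORS_4 = ((-1, 0), (0, 1), (1, 0), (0, -1))


@dataclass
class LabelField:
    """Per-pixel automaton state on one slice."""

    labels: np.ndarray  # int8, values in {UNLABELED, FOREGROUND, BACKGROUND}
    strength: np.ndarray  # float, θ ∈ [0, 1]
    feature: np.ndarray  # float, normalized slice intensity
    converged: bool = False
    n_iterations: int = 0

    def copy(self) -> "LabelField":
        return LabelField(
            labels=self.labels.copy(),
            strength=self.strength.copy(),
            feature=self.feature,
            converged=self.converged,
            n_iterations=self.n_iterations,
        )


@dataclass(frozen=True)
class AutomatonConfig:
    neighborhood: int = 8  # 4- or 8-connected
    lam: float = 1.0  # per-step distance attenuation λ ∈ (0, 1]
    max_iterations: int | None = None  # default: rows × cols
    seed_erode_px: int = 2
    background_dilate_px: int = 10
    motion_percentile: float = 50.0

    def __post_init__(self) -> None:
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if not 0 < self.lam <= 1:
            raise ValueError("lam must lie in (0, 1]")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return _NEIGHBORS_8 if self.neighborhood == 8 else _NEIGHBORS_4


def normalize_slice(slice_image: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant slice maps to all zeros."""
    img = np.asarray(slice_image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def init_labels(
    slice_image: np.ndarray,
    seed_contour: Contour,
    stack: CineStack,
    phase: int,
    config: AutomatonConfig | None = None,
) -> LabelField:
    """Seed the automaton from a rough endocardial contour.

    Foreground seeds: pixels inside the seed polygon eroded by
    ``seed_erode_px`` (guards against the rough contour overshooting the
    blood pool).  Background seeds: the one-pixel image border, plus pixels
    outside the polygon dilated by ``background_dilate_px`` whose temporal
    intensity standard deviation (across all phases of this slice) falls at
    or below the ``motion_percentile``-th percentile of the motion map —
    static tissue far from the moving heart.
    """
    config = config or AutomatonConfig()
    img = np.asarray(slice_image, dtype=float)
    rows, cols = img.shape
    inside = rasterize(seed_contour, (rows, cols)).mask
    fg = ndimage.binary_erosion(inside, structure=disk(config.seed_erode_px)) \
        if config.seed_erode_px > 0 else inside
    if not fg.any():
        raise ValueError(
            "seed contour too small: erosion removed every foreground seed; draw a larger seed"
        )
    motion = np.std(stack.intensities[:, seed_contour.slice], axis=0)
    static = motion <= np.percentile(motion, config.motion_percentile)
    dilated = ndimage.binary_dilation(inside, structure=disk(config.background_dilate_px)) \
        if config.background_dilate_px > 0 else inside
    bg = ~dilated & static
    bg[0, :] = bg[-1, :] = True
    bg[:, 0] = bg[:, -1] = True
    bg &= ~fg

    labels = np.full((rows, cols), UNLABELED, dtype=np.int8)
    labels[bg] = BACKGROUND
    labels[fg] = FOREGROUND
    strength = np.where(labels != UNLABELED, 1.0, 0.0)
    return LabelField(labels=labels, strength=strength, feature=normalize_slice(img))


def _shift(a: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """out[r, c] = a[r + dr, c + dc], with ``fill`` outside the grid."""
    out = np.full_like(a, fill)
    rows, cols = a.shape
    rs_dst = slice(max(-dr, 0), rows - max(dr, 0))
    cs_dst = slice(max(-dc, 0), cols - max(dc, 0))
    rs_src = slice(max(dr, 0), rows - max(-dr, 0))
    cs_src = slice(max(dc, 0), cols - max(-dc, 0))
    out[rs_dst, cs_dst] = a[rs_src, cs_src]
    return out


def evolve(field: LabelField, config: AutomatonConfig | None = None) -> LabelField:
    """Run the synchronous conquest iteration to its fixpoint.

    Returns a new field; θ is non-decreasing at every pixel, and re-running
    on a converged field changes nothing.
    """
    config = config or AutomatonConfig()
    labels = field.labels
    if not (labels == FOREGROUND).any() or not (labels == BACKGROUND).any():
        raise ValueError("evolve requires at least one foreground and one background seed")
    theta = field.strength.astype(float)
    labels = labels.copy()
    feat = field.feature
    # per-direction attenuation λ·g(|I_p − I_q|); zero across the image border
    atten = []
    for dr, dc in config.offsets:
        g = config.lam * (1.0 - np.abs(feat - _shift(feat, dr, dc, np.inf)))
        atten.append(np.clip(g, 0.0, None))

    rows, cols = labels.shape
    max_iter = config.max_iterations or rows * cols
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        best_attack = np.zeros_like(theta)
        best_label = np.zeros_like(labels)
        for g, (dr, dc) in zip(atten, config.offsets):
            lbl_q = _shift(labels, dr, dc, UNLABELED)
            attack = g * _shift(theta, dr, dc, 0.0)
            attack[lbl_q == UNLABELED] = 0.0
            better = attack > best_attack  # strict: earlier directions win ties
            best_attack[better] = attack[better]
            best_label[better] = lbl_q[better]
        conquered = (best_attack > theta) & (best_label != UNLABELED)
        if not conquered.any():
            converged = True
            break
        labels[conquered] = best_label[conquered]
        theta[conquered] = best_attack[conquered]
    return LabelField(
        labels=labels, strength=theta, feature=feat, converged=converged, n_iterations=it
    )


def extract_contour(
    field: LabelField,
    phase: int,
    slice_index: int,
    n_points: int = 120,
) -> Contour:
    """Boundary contour of the foreground: largest 8-connected component,
    holes filled, sub-pixel 0.5-level boundary, resampled and lightly smoothed."""
    fg = field.labels == FOREGROUND
    if not fg.any():
        raise ValueError("no foreground pixels to contour")
    comp = measure.label(fg, connectivity=2)
    largest = comp == np.argmax(np.bincount(comp.ravel())[1:]) + 1
    filled = ndimage.binary_fill_holes(largest)
    padded = np.pad(filled.astype(float), 1)
    curves = measure.find_contours(padded, 0.5)
    boundary = max(curves, key=len) - 1.0  # unpad; (row, col)
    pts = boundary[:, ::-1]  # -> (x, y)
    pts = _resample_closed(pts, n_points)
    pts = _smooth_closed(pts, passes=1)
    return Contour(phase, slice_index, "rv_endo", pts)


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Equal-arc-length resampling of a closed polyline to n points."""
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    t = np.linspace(0.0, arclen[-1], n, endpoint=False)
    return np.column_stack(
        [np.interp(t, arclen, closed[:, 0]), np.interp(t, arclen, closed[:, 1])]
    )


def _smooth_closed(pts: np.ndarray, passes: int = 1) -> np.ndarray:
    """3-point circular moving average."""
    for _ in range(passes):
        pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    return pts


def optimize_seed(
    slice_image: np.ndarray,
    rough_seed: Contour,
    stack: CineStack,
    phase: int,
    config: AutomatonConfig | None = None,
    return_info: bool = False,
):
    """Refine a rough seed contour: seed, evolve, extract.

    The refined contour replaces the user's seed for inter-slice propagation.
    With ``return_info=True`` also returns a dict with the converged field
    and quality warnings (currently: refined area more than 300% above the
    seed area, the signature of a seed dropped into homogeneous background).
    """
    config = config or AutomatonConfig()
    field = init_labels(slice_image, rough_seed, stack, phase, config)
    field = evolve(field, config)
    contour = extract_contour(field, phase, rough_seed.slice)
    warnings: list[str] = []
    seed_area = rough_seed.area_px2()
    if seed_area > 0 and contour.area_px2() > 4.0 * seed_area:
        warnings.append("area_change_gt_300_percent")
    if return_info:
        return contour, {"field": field, "warnings": warnings}
    return contour
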