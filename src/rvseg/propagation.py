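"""Inter-slice propagation of the optimized seed contour, with misalignment
correction and LV-epicardium attachment.

From the seeded slice the segmentation marches toward the basal slice and
toward the apical slice.  For each next slice the previous slice's final
contour is translated by the integer-pixel shift that maximizes normalized
cross-correlation between the two slices (breath-hold misregistration),
shrunk by an apex-ward area-decay prior when marching toward the apex, and
used as the rough seed for the automaton on that slice.  The geometry prior
is deliberately minimal — the method is image-driven, not model-based.

When LV contours are available the resulting RV endocardial contour is
attached to the LV epicardial contour so the two effectively share the
septum: the part of the RV polygon inside the LV epicardium is replaced by
the epicardial arc between the two junction points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon

from .automaton import AutomatonConfig, optimize_seed
from .io_formats import CineStack, Contour, ContourSet, StudyAnnotations

__all__ = [
    "PropagationConfig",
    "align_adjacent",
    "propagate_phase",
    "attach_to_lv",
]


@dataclass(frozen=True)
class PropagationConfig:
    search_radius_mm: float = 10.0
    apical_area_decay: float = 0.55  # fallback per-slice seed-area factor apex-ward
    min_area_px: float = 10.0
    align: bool = True
    window_margin_px: int = 8  # window = seed bounding box grown by this margin
    # isotropic size ratios tried jointly with the translation; anatomy both
    # tapers toward the apex (ratios < 1) and grows toward the base (> 1)
    scale_search: tuple[float, ...] = (
        0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00, 1.05, 1.10, 1.15,
    )

    def __post_init__(self) -> None:
        if not 0 < self.apical_area_decay <= 1:
            raise ValueError("apical_area_decay must lie in (0, 1]")
        if self.search_radius_mm < 0:
            raise ValueError("search_radius_mm must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    shift: tuple[int, int]  # (dx, dy) in pixels
    scale: float  # best in-plane size ratio slice_a -> slice_b
    degenerate: bool = False


def align_adjacent(
    slice_a: np.ndarray,
    slice_b: np.ndarray,
    window: tuple[slice, slice],
    config: PropagationConfig | None = None,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> AlignmentResult:
    """Integer-pixel (dx, dy) mapping content of ``slice_a`` onto ``slice_b``.

    Maximizes the normalized cross-correlation of the window between the two
    slices, searched jointly over translations within the search radius and
    a small set of isotropic size ratios.  The scale search decouples true
    breath-hold misregistration from the apparent shift a plain translation
    matcher reads into anatomy that tapers toward the apex (the ventricle
    shrinks about its own center, which a translation alone cannot model).
    Translation ties are broken by the smallest |shift|, then scan order.
    A degenerate (constant) window returns shift (0, 0) with the
    ``degenerate`` flag raised.
    """
    config = config or PropagationConfig()
    a = np.asarray(slice_a, dtype=float)
    b = np.asarray(slice_b, dtype=float)
    rs, cs = window
    if a[rs, cs].std() == 0:
        return AlignmentResult((0, 0), 1.0, True)
    rows, cols = b.shape
    row_mm, col_mm = pixel_spacing_mm
    max_dr = int(config.search_radius_mm / row_mm)
    max_dc = int(config.search_radius_mm / col_mm)
    # candidate shifts sorted by |shift| then scan order -> first strict max wins
    cands = [
        (np.hypot(dr * row_mm, dc * col_mm), i, dr, dc)
        for i, (dr, dc) in enumerate(
            (dr, dc) for dr in range(-max_dr, max_dr + 1) for dc in range(-max_dc, max_dc + 1)
        )
    ]
    cands.sort()
    center = np.array([(rs.start + rs.stop - 1) / 2.0, (cs.start + cs.stop - 1) / 2.0])
    best_score, best_shift, best_scale = -np.inf, (0, 0), 1.0
    for f in config.scale_search:
        if f == 1.0:
            a_f = a
        else:
            a_f = ndimage.affine_transform(
                a, np.diag([1.0 / f, 1.0 / f]), offset=center - center / f,
                order=1, mode="nearest",
            )
        patch = a_f[rs, cs]
        std = patch.std()
        if std == 0:
            continue
        patch = (patch - patch.mean()) / std
        for _, _, dr, dc in cands:
            r0, r1 = rs.start + dr, rs.stop + dr
            c0, c1 = cs.start + dc, cs.stop + dc
            if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
                continue
            target = b[r0:r1, c0:c1]
            tstd = target.std()
            if tstd == 0:
                continue
            score = float(np.mean(patch * (target - target.mean()) / tstd))
            if score > best_score:
                best_score, best_shift, best_scale = score, (dc, dr), f
    if not np.isfinite(best_score):
        return AlignmentResult((0, 0), 1.0, True)
    return AlignmentResult(best_shift, best_scale, False)


def _contour_window(contour: Contour, shape: tuple[int, int], margin: int) -> tuple[slice, slice]:
    pts = contour.points
    r0 = max(int(np.floor(pts[:, 1].min())) - margin, 0)
    r1 = min(int(np.ceil(pts[:, 1].max())) + margin + 1, shape[0])
    c0 = max(int(np.floor(pts[:, 0].min())) - margin, 0)
    c1 = min(int(np.ceil(pts[:, 0].max())) + margin + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def propagate_phase(
    stack: CineStack,
    phase: int,
    annotations: StudyAnnotations,
    optimized_seed: Contour,
    seed_slice: int,
    automaton_config: AutomatonConfig | None = None,
    propagation_config: PropagationConfig | None = None,
    lv_contours: ContourSet | None = None,
) -> ContourSet:
    """Segment every slice between the apical and basal annotation bounds.

    ``optimized_seed`` is the already-refined contour on ``seed_slice``
    (see :func:`rvseg.automaton.optimize_seed`).  Slices whose segmentation
    falls below the minimum area are omitted with a warning.  When
    ``lv_contours`` holds an lv_epi contour for a slice, the RV result is
    attached to it.
    """
    acfg = automaton_config or AutomatonConfig()
    pcfg = propagation_config or PropagationConfig()
    apical, basal = annotations.slice_range(phase)
    lo, hi = min(apical, basal), max(apical, basal)
    if not lo <= seed_slice <= hi:
        raise ValueError(
            f"seed slice {seed_slice} outside the annotated range [{lo}, {hi}] of phase {phase}"
        )
    result = ContourSet.from_stack(stack)
    results: dict[int, Contour] = {seed_slice: replace(optimized_seed, phase=phase, slice=seed_slice)}

    def march(target: int, apexward: bool) -> None:
        step = 1 if target >= seed_slice else -1
        prev = seed_slice
        for s in range(seed_slice + step, target + step, step):
            prev_contour = results.get(prev)
            if prev_contour is None:
                break
            seed = prev_contour
            scaled = False
            if pcfg.align:
                window = _contour_window(prev_contour, stack.intensities.shape[2:], pcfg.window_margin_px)
                res = align_adjacent(
                    stack.intensities[phase, prev],
                    stack.intensities[phase, s],
                    window,
                    pcfg,
                    stack.pixel_spacing_mm,
                )
                if not res.degenerate:
                    # same transform the matcher scored: scale about the
                    # window center, then translate
                    rs, cs = window
                    c_w = ((cs.start + cs.stop - 1) / 2.0, (rs.start + rs.stop - 1) / 2.0)
                    seed = seed.scaled(res.scale, about=c_w).translated(*res.shift)
                    scaled = True
            if apexward and not scaled:
                seed = seed.scaled(np.sqrt(pcfg.apical_area_decay))
            seed = replace(seed, slice=s, phase=phase)
            contour = optimize_seed(stack.intensities[phase, s], seed, stack, phase, acfg)
            contour = replace(contour, phase=phase, slice=s)
            if contour.area_px2() < pcfg.min_area_px:
                result.warnings.append(
                    f"phase {phase} slice {s}: segmented area below minimum, slice omitted"
                )
                break
            results[s] = contour
            prev = s

    march(apical, apexward=True)
    march(basal, apexward=False)

    for s, contour in sorted(results.items()):
        if lv_contours is not None:
            lv_epi = lv_contours.get(phase, s, "lv_epi")
            if lv_epi is not None:
                contour, _ = attach_to_lv(contour, lv_epi)
        result.add(contour)
    return result


def attach_to_lv(rv: Contour, lv_epi: Contour) -> tuple[Contour, list[str]]:
    """Attach the RV endocardial contour to the LV epicardial contour.

    The part of the RV polygon lying inside the LV epicardium is removed and
    replaced by the epicardial arc between the two junction points, so the
    two contours share the septum and their interiors do not overlap.
    Disjoint contours are returned unchanged with a ``no_attachment`` flag;
    a pathological overlap producing more than one piece keeps the largest
    piece and raises a ``multi_junction`` flag.
    """
    if (rv.phase, rv.slice) != (lv_epi.phase, lv_epi.slice):
        raise ValueError("contours must belong to the same (phase, slice)")
    rv_poly = rv.polygon().buffer(0)
    lv_poly = lv_epi.polygon().buffer(0)
    flags: list[str] = []
    if not rv_poly.intersects(lv_poly):
        return rv, ["no_attachment"]
    diff = rv_poly.difference(lv_poly)
    if diff.is_empty:
        return rv, ["no_attachment"]
    if isinstance(diff, MultiPolygon):
        flags.append("multi_junction")
        diff = max(diff.geoms, key=lambda g: g.area)
    pts = np.asarray(diff.exterior.coords)[:-1]
    if pts.shape[0] < 3:
        return rv, ["no_attachment"]
    return replace(rv, points=pts), flags
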