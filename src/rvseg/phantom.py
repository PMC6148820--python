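"""Synthetic short-axis cine phantom with analytic ground truth.

The phantom emulates an SSFP-like short-axis acquisition of a healthy adult
heart: bright blood pool, darker myocardium, dark background; 8 mm slices
with a 2 mm interslice gap, 1.25 mm in-plane pixels, 24 reconstructed phases.
Geometry is deliberately simple so every area has a closed form:

* the LV endocardium and epicardium are concentric discs;
* the RV endocardium is the lune between an off-center outer disc and the
  LV-epicardial disc, so the RV inner border follows the LV epicardium and
  the two structures share the septum, as on real short-axis images;
* radii taper quadratically toward the apex, and all radii follow a smooth
  cosine time course from end-diastole to end-systole and back;
* each slice may receive a random in-plane translation, constant across
  phases, emulating breath-hold misregistration — applied to both the image
  and the ground-truth contours;
* i.i.d. Gaussian noise is added on top of the three tissue intensity levels.

Default sizes are chosen so the ground-truth RV end-diastolic volume is about
166 mL and the ejection fraction about 55%, typical of healthy adults.
Trabeculae and papillary muscles are not simulated: clinical convention
includes them in the blood-pool volume, so a clean blood pool is the correct
ground truth.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    CineStack,
    Contour,
    ContourSet,
    StudyAnnotations,
    write_annotations,
    write_cine,
    write_contours,
)
from .volumetrics import VolumeSet, volumes_from_contours

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "perturb_seed",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, physiology and acquisition parameters of the phantom.

    Lengths are mm at end-diastole in the basal-most ventricular slice;
    contractions are area fractions (0.55 means the ES area is 45% of ED).
    """

    # acquisition
    n_phases: int = 24
    n_slices: int = 10
    image_shape: tuple[int, int] = (128, 128)  # (rows, cols)
    pixel_spacing_mm: tuple[float, float] = (1.25, 1.25)
    slice_thickness_mm: float = 8.0
    interslice_gap_mm: float = 2.0
    es_phase: int = 9
    basal_slice: int = 1
    apical_slice: int = 8
    # geometry (mm, ED, base)
    lv_center_offset_mm: tuple[float, float] = (20.0, 0.0)  # (x, y) from image center
    lv_endo_radius_mm: float = 19.0
    lv_wall_mm: float = 9.0
    rv_outer_radius_mm: float = 40.0
    rv_center_distance_mm: float = 24.0
    rv_wall_mm: float = 4.0
    # physiology
    rv_contraction: float = 0.55  # ED->ES area fraction lost (RV + LV epi scale)
    lv_contraction: float = 0.60  # LV endocardial area fraction lost
    apical_taper: float = 0.57  # quadratic radius-taper strength toward the apex
    # degradation
    shift_mm: float = 2.0  # max per-slice in-plane shift magnitude
    noise_sd: float = 0.04
    # intensities (arbitrary units)
    intensity_blood: float = 1.0
    intensity_myocardium: float = 0.35
    intensity_background: float = 0.12
    rng_seed: int = 0
    contour_points: int = 160

    def __post_init__(self) -> None:
        if not (0 < self.rv_contraction < 1 and 0 < self.lv_contraction < 1):
            raise ValueError("contraction fractions must lie in (0, 1)")
        if self.noise_sd < 0 or self.shift_mm < 0:
            raise ValueError("noise_sd and shift_mm must be >= 0")
        for name in (
            "lv_endo_radius_mm",
            "lv_wall_mm",
            "rv_outer_radius_mm",
            "rv_center_distance_mm",
            "rv_wall_mm",
            "slice_thickness_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.es_phase < self.n_phases:
            raise ValueError("es_phase out of range")
        if not (0 <= self.basal_slice < self.n_slices and 0 <= self.apical_slice < self.n_slices):
            raise ValueError("slice annotations out of range")
        r1, r2, d = self.rv_outer_radius_mm, self.lv_epi_radius_mm, self.rv_center_distance_mm
        if not abs(r1 - r2) < d < r1 + r2:
            raise ValueError(
                "RV and LV-epicardial circles must partially overlap: need "
                f"|{r1} - {r2}| < {d} < {r1} + {r2}"
            )
        # full ED geometry (plus shifts) must stay inside the field of view
        half_x = self.image_shape[1] * self.pixel_spacing_mm[1] / 2.0
        half_y = self.image_shape[0] * self.pixel_spacing_mm[0] / 2.0
        cx, cy = self.lv_center_offset_mm
        reach_x = max(abs(cx) + r2, abs(cx - d) + r1 + self.rv_wall_mm) + self.shift_mm
        reach_y = max(abs(cy) + r2, abs(cy) + r1 + self.rv_wall_mm) + self.shift_mm
        if reach_x >= half_x or reach_y >= half_y:
            raise ValueError("phantom geometry exceeds the field of view")

    @property
    def lv_epi_radius_mm(self) -> float:
        return self.lv_endo_radius_mm + self.lv_wall_mm

    @property
    def ed_phase(self) -> int:
        return 0

    @property
    def ventricular_slices(self) -> list[int]:
        return list(range(self.basal_slice, self.apical_slice + 1))

    # -- smooth ED -> ES -> ED time course --------------------------------

    def systolic_weight(self, phase: int) -> float:
        """0 at ED, 1 at ES, cosine-smooth in between (and back)."""
        es, n = self.es_phase, self.n_phases
        if phase <= es:
            return (1.0 - np.cos(np.pi * phase / es)) / 2.0
        return (1.0 + np.cos(np.pi * (phase - es) / (n - es))) / 2.0

    def taper(self, slice_index: int) -> float:
        """Linear-size factor of a ventricular slice (1 at the base)."""
        n = self.apical_slice - self.basal_slice
        if n == 0:
            return 1.0
        u = (slice_index - self.basal_slice) / n
        return 1.0 - self.apical_taper * u * u

    def scale(self, phase: int, slice_index: int, structure: str = "rv_endo") -> float:
        """Overall linear-size factor at (phase, slice) for a structure group."""
        cf = self.lv_contraction if structure == "lv_endo" else self.rv_contraction
        sigma = np.sqrt(1.0 - cf * self.systolic_weight(phase))
        return float(self.taper(slice_index) * sigma)

    # -- closed-form areas / volumes --------------------------------------

    def lv_center_px(self) -> np.ndarray:
        """(x, y) pixel coordinates of the unshifted LV center."""
        rows, cols = self.image_shape
        row_mm, col_mm = self.pixel_spacing_mm
        cx, cy = self.lv_center_offset_mm
        return np.array([(cols - 1) / 2.0 + cx / col_mm, (rows - 1) / 2.0 + cy / row_mm])

    def rv_lune_area_mm2(self, phase: int, slice_index: int) -> float:
        """Closed-form RV endocardial area: off-center disc minus LV-epi disc."""
        u = self.scale(phase, slice_index)
        r1 = self.rv_outer_radius_mm * u
        r2 = self.lv_epi_radius_mm * u
        d = self.rv_center_distance_mm * u
        return np.pi * r1 * r1 - _disc_intersection_area(r1, r2, d)

    def analytic_volume_ml(self, phase: int) -> float:
        """Closed-form RV volume at a phase: Σ slice lune areas × thickness."""
        t = self.slice_thickness_mm + self.interslice_gap_mm
        return sum(self.rv_lune_area_mm2(phase, s) for s in self.ventricular_slices) * t / 1000.0

    def annotations(self) -> StudyAnnotations:
        return StudyAnnotations(
            ed_phase=self.ed_phase,
            es_phase=self.es_phase,
            ed_apical_slice=self.apical_slice,
            ed_basal_slice=self.basal_slice,
            es_apical_slice=self.apical_slice,
            es_basal_slice=self.basal_slice,
        )


@dataclass
class PhantomDataset:
    stack: CineStack
    truth: ContourSet
    annotations: StudyAnnotations
    truth_volumes: VolumeSet
    slice_shifts_px: np.ndarray  # (n_slices, 2) applied (dx, dy) in pixels
    spec: PhantomSpec = field(repr=False, default=None)


def _disc_intersection_area(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two discs with radii r1, r2 and center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    return r1 * r1 * a1 + r2 * r2 * a2 - 0.5 * np.sqrt(k)


def _lune_polygon(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float, n_points: int
) -> np.ndarray:
    """Boundary polygon of disc(c1, r1) minus disc(c2, r2), for partial overlap.

    The boundary is the outer arc of circle 1 joined to the (septal) arc of
    circle 2 between the two junction points.
    """
    delta = c2 - c1
    d = float(np.hypot(*delta))
    alpha = float(np.arctan2(delta[1], delta[0]))
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    delta1 = np.arctan2(h, a)  # half-angle of circle-1 arc inside circle 2
    b = (d * d + r2 * r2 - r1 * r1) / (2 * d)
    gamma = np.arctan2(h, -b)  # junction angle on circle 2 relative to alpha
    # split points across the two arcs in proportion to arc length
    len1 = r1 * (2 * np.pi - 2 * delta1)
    len2 = r2 * 2 * (np.pi - gamma)
    n1 = max(int(round(n_points * len1 / (len1 + len2))), 8)
    n2 = max(n_points - n1, 8)
    # outer arc of circle 1: CCW from alpha+delta1 to alpha+2pi-delta1
    t1 = np.linspace(alpha + delta1, alpha + 2 * np.pi - delta1, n1, endpoint=True)
    outer = c1 + r1 * np.column_stack([np.cos(t1), np.sin(t1)])
    # septal arc of circle 2: from alpha+2pi-gamma down to alpha+gamma (through alpha+pi)
    t2 = np.linspace(alpha + 2 * np.pi - gamma, alpha + gamma, n2 + 2, endpoint=True)
    septal = c2 + r2 * np.column_stack([np.cos(t2[1:-1]), np.sin(t2[1:-1])])
    return np.vstack([outer, septal])


def _circle_polygon(center: np.ndarray, radius: float, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    return center + radius * np.column_stack([np.cos(t), np.sin(t)])


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Render the cine stack and its exact ground-truth contours.

    The same seed always produces bit-identical output.  With ``noise_sd = 0``
    and ``shift_mm = 0`` every pixel takes exactly one of the three tissue
    intensity levels.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.image_shape
    row_mm, col_mm = spec.pixel_spacing_mm
    # one in-plane shift per slice, constant across phases (per-breath-hold)
    shifts_px = np.zeros((spec.n_slices, 2))
    if spec.shift_mm > 0:
        angles = rng.uniform(0.0, 2 * np.pi, size=spec.n_slices)
        radii = rng.uniform(0.0, spec.shift_mm, size=spec.n_slices)
        shifts_px[:, 0] = radii * np.cos(angles) / col_mm
        shifts_px[:, 1] = radii * np.sin(angles) / row_mm

    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    c_lv0 = spec.lv_center_px()
    data = np.full((spec.n_phases, spec.n_slices, rows, cols), spec.intensity_background)

    vslices = set(spec.ventricular_slices)
    for s in range(spec.n_slices):
        if s not in vslices:
            continue
        c_lv = c_lv0 + shifts_px[s]
        for p in range(spec.n_phases):
            u = spec.scale(p, s)
            u_lv = spec.scale(p, s, "lv_endo")
            r_endo = spec.lv_endo_radius_mm * u_lv / col_mm
            r_epi = spec.lv_epi_radius_mm * u / col_mm
            r_rv = spec.rv_outer_radius_mm * u / col_mm
            r_rvw = (spec.rv_outer_radius_mm + spec.rv_wall_mm) * u / col_mm
            c_rv = c_lv - np.array([spec.rv_center_distance_mm * u / col_mm, 0.0])
            d_lv2 = (xs - c_lv[0]) ** 2 + (ys - c_lv[1]) ** 2
            d_rv2 = (xs - c_rv[0]) ** 2 + (ys - c_rv[1]) ** 2
            in_endo = d_lv2 <= r_endo**2
            in_epi = d_lv2 <= r_epi**2
            in_rv = d_rv2 <= r_rv**2
            in_rvw = d_rv2 <= r_rvw**2
            lune = in_rv & ~in_epi
            myo = (in_epi & ~in_endo) | (in_rvw & ~in_epi & ~lune)
            blood = in_endo | lune
            img = data[p, s]
            img[myo] = spec.intensity_myocardium
            img[blood] = spec.intensity_blood

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    stack = CineStack(
        intensities=data,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        interslice_gap_mm=spec.interslice_gap_mm,
    )
    annotations = spec.annotations()

    truth = ContourSet.from_stack(stack)
    for p in sorted({annotations.ed_phase, annotations.es_phase}):
        for s in spec.ventricular_slices:
            c_lv = c_lv0 + shifts_px[s]
            u = spec.scale(p, s)
            u_lv = spec.scale(p, s, "lv_endo")
            r_epi = spec.lv_epi_radius_mm * u / col_mm
            r_rv = spec.rv_outer_radius_mm * u / col_mm
            c_rv = c_lv - np.array([spec.rv_center_distance_mm * u / col_mm, 0.0])
            truth.add(
                Contour(p, s, "rv_endo", _lune_polygon(c_rv, r_rv, c_lv, r_epi, spec.contour_points))
            )
            truth.add(
                Contour(
                    p, s, "lv_endo",
                    _circle_polygon(c_lv, spec.lv_endo_radius_mm * u_lv / col_mm, 120),
                )
            )
            truth.add(Contour(p, s, "lv_epi", _circle_polygon(c_lv, r_epi, 120)))

    truth_volumes = volumes_from_contours(truth, annotations)
    return PhantomDataset(
        stack=stack,
        truth=truth,
        annotations=annotations,
        truth_volumes=truth_volumes,
        slice_shifts_px=shifts_px,
        spec=spec,
    )


def perturb_seed(
    truth_contour: Contour,
    magnitude_mm: float,
    rng_seed: int,
    pixel_spacing_mm: tuple[float, float] = (1.25, 1.25),
    n_modes: int = 4,
    max_retries: int = 20,
) -> Contour:
    """Smooth radial perturbation of a contour — a reproducible careless seed.

    Each point is displaced radially (about the centroid) by a low-order
    Fourier series of its polar angle, normalized so the maximum displacement
    equals ``magnitude_mm``; the result is re-drawn (bounded retries) if it
    self-intersects.  Magnitude 0 returns the input unchanged.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if magnitude_mm == 0:
        return truth_contour
    step_px = magnitude_mm / float(np.mean(pixel_spacing_mm))
    rng = np.random.default_rng(rng_seed)
    center = truth_contour.centroid()
    rel = truth_contour.points - center
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    r = np.hypot(rel[:, 0], rel[:, 1])
    for _ in range(max_retries):
        amps = rng.normal(size=n_modes)
        phases = rng.uniform(0.0, 2 * np.pi, size=n_modes)
        delta = np.zeros_like(phi)
        for k in range(1, n_modes + 1):
            delta += amps[k - 1] * np.cos(k * phi + phases[k - 1])
        peak = np.abs(delta).max()
        if peak == 0:
            continue
        delta *= step_px / peak
        r_new = np.maximum(r + delta, 0.1 * r)
        pts = center + np.column_stack([r_new * np.cos(phi), r_new * np.sin(phi)])
        candidate = Contour(
            truth_contour.phase, truth_contour.slice, truth_contour.structure, pts
        )
        if candidate.is_simple():
            return candidate
    raise RuntimeError("could not draw a simple perturbed contour within the retry budget")


def write_dataset(ds: PhantomDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write stack NIfTI, truth contours JSON, annotations JSON and truth-volume CSV."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.nii.gz",
        "truth_contours": out / "truth_contours.json",
        "annotations": out / "annotations.json",
        "truth_volumes": out / "truth_volumes.csv",
    }
    write_cine(ds.stack, paths["stack"])
    write_contours(ds.truth, paths["truth_contours"])
    write_annotations(ds.annotations, paths["annotations"])
    pd.DataFrame(
        [
            {"subject": "phantom", "parameter": "ed_volume_ml", "value": ds.truth_volumes.ed_volume_ml},
            {"subject": "phantom", "parameter": "es_volume_ml", "value": ds.truth_volumes.es_volume_ml},
            {"subject": "phantom", "parameter": "ef_percent", "value": ds.truth_volumes.ef_percent},
        ]
    ).to_csv(paths["truth_volumes"], index=False)
    return paths
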