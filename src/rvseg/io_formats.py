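"""Fixed, versioned on-disk formats for cine stacks, annotations and contours.

Conventions used throughout the package:

* all indices (phase, slice, row, col) are 0-based;
* contour points are continuous pixel coordinates with ``(x, y) = (col, row)``;
  physical millimetres are obtained by multiplying by the pixel spacing;
* contours are implicitly closed (the last point connects back to the first);
* slice thickness and interslice gap are stored separately; the effective
  per-slice thickness used for volumetry is ``thickness + gap``.

Cine stacks are stored as NIfTI-1 with file axes ``(col, row, slice, phase)``
and an optional ``*.meta.json`` sidecar separating slice thickness from the
interslice gap (the NIfTI slice pixdim holds their sum).  Contour sets and
study annotations are plain JSON with the schemas documented on the writer
functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "CineStack",
    "StudyAnnotations",
    "Contour",
    "ContourSet",
    "STRUCTURES",
    "read_cine",
    "write_cine",
    "read_contours",
    "write_contours",
    "read_annotations",
    "write_annotations",
]

STRUCTURES = ("rv_endo", "lv_endo", "lv_epi")

_SIDECAR_SUFFIX = ".meta.json"


@dataclass(frozen=True)
class CineStack:
    """A 4D short-axis cine image with physical spacing metadata.

    ``intensities`` is indexed ``(phase, slice, row, col)`` in arbitrary
    non-negative units.
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]  # (row_mm, col_mm)
    slice_thickness_mm: float
    interslice_gap_mm: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"expected 4 dimensions (phase, slice, row, col), got {arr.ndim}")
        if any(d < 1 for d in arr.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", arr)
        r, c = self.pixel_spacing_mm
        if not (r > 0 and c > 0):
            raise ValueError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")
        object.__setattr__(self, "pixel_spacing_mm", (float(r), float(c)))
        if not self.slice_thickness_mm > 0:
            raise ValueError(f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm}")
        if self.interslice_gap_mm < 0:
            raise ValueError(f"interslice_gap_mm must be >= 0, got {self.interslice_gap_mm}")

    @property
    def n_phases(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[2]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[3]

    @property
    def effective_slice_thickness_mm(self) -> float:
        """Per-slice thickness for volumetry: slice thickness plus gap."""
        return self.slice_thickness_mm + self.interslice_gap_mm


@dataclass(frozen=True)
class StudyAnnotations:
    """ED/ES phase indices and the apical/basal slice range at each phase.

    The slice index is not assumed to increase toward the apex: operations
    iterate from ``basal_slice`` to ``apical_slice`` regardless of which is
    numerically larger.  ``apical == basal`` denotes a single-slice ventricle.
    """

    ed_phase: int
    es_phase: int
    ed_apical_slice: int
    ed_basal_slice: int
    es_apical_slice: int
    es_basal_slice: int

    def validate_against(self, stack: CineStack) -> None:
        for name in ("ed_phase", "es_phase"):
            v = getattr(self, name)
            if not 0 <= v < stack.n_phases:
                raise ValueError(f"{name}={v} out of range [0, {stack.n_phases})")
        for name in ("ed_apical_slice", "ed_basal_slice", "es_apical_slice", "es_basal_slice"):
            v = getattr(self, name)
            if not 0 <= v < stack.n_slices:
                raise ValueError(f"{name}={v} out of range [0, {stack.n_slices})")

    def phase_index(self, phase: str | int) -> int:
        """Resolve ``"ed"``/``"es"`` (or a raw index) to a phase index."""
        if phase == "ed":
            return self.ed_phase
        if phase == "es":
            return self.es_phase
        return int(phase)

    def slice_range(self, phase: str | int) -> tuple[int, int]:
        """(apical, basal) slice indices for the given phase."""
        p = self.phase_index(phase)
        if p == self.ed_phase:
            return self.ed_apical_slice, self.ed_basal_slice
        if p == self.es_phase:
            return self.es_apical_slice, self.es_basal_slice
        raise ValueError(f"phase {p} has no annotated slice range (only ED/ES are annotated)")

    def slices(self, phase: str | int) -> list[int]:
        """All slice indices from basal to apical, inclusive, in marching order."""
        apical, basal = self.slice_range(phase)
        step = 1 if apical >= basal else -1
        return list(range(basal, apical + step, step))


@dataclass(frozen=True)
class Contour:
    """An ordered, implicitly-closed planar polygon bound to (phase, slice, structure).

    Points are ``(x, y) = (col, row)`` in continuous pixel units.
    """

    phase: int
    slice: int
    structure: str
    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        # A repeated final point (explicitly closed input) is dropped.
        if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if pts.shape[0] < 3:
            raise ValueError(f"a contour needs >= 3 points, got {pts.shape[0]}")
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.phase, self.slice, self.structure)

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def is_simple(self) -> bool:
        return self.polygon().is_valid

    def area_px2(self) -> float:
        """Enclosed area in pixel² (shoelace, orientation independent)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon().centroid.coords[0])

    def translated(self, dx: float, dy: float) -> "Contour":
        return replace(self, points=self.points + np.array([dx, dy]))

    def scaled(self, factor: float, about: Sequence[float] | None = None) -> "Contour":
        """Scale linearly by ``factor`` about ``about`` (default: centroid)."""
        c = self.centroid() if about is None else np.asarray(about, dtype=float)
        return replace(self, points=c + factor * (self.points - c))


@dataclass
class ContourSet:
    """A keyed collection of contours with the source stack's spacing metadata."""

    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    interslice_gap_mm: float
    contours: list[Contour] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, str]] = set()
        for c in self.contours:
            if c.key in seen:
                raise ValueError(f"duplicate contour for (phase, slice, structure) = {c.key}")
            seen.add(c.key)

    @classmethod
    def from_stack(cls, stack: CineStack, contours: Iterable[Contour] = ()) -> "ContourSet":
        return cls(
            pixel_spacing_mm=stack.pixel_spacing_mm,
            slice_thickness_mm=stack.slice_thickness_mm,
            interslice_gap_mm=stack.interslice_gap_mm,
            contours=list(contours),
        )

    @property
    def effective_slice_thickness_mm(self) -> float:
        return self.slice_thickness_mm + self.interslice_gap_mm

    def add(self, contour: Contour) -> None:
        if any(c.key == contour.key for c in self.contours):
            raise ValueError(f"duplicate contour for (phase, slice, structure) = {contour.key}")
        self.contours.append(contour)

    def get(self, phase: int, slice_index: int, structure: str = "rv_endo") -> Contour | None:
        for c in self.contours:
            if c.key == (phase, slice_index, structure):
                return c
        return None

    def select(self, phase: int | None = None, structure: str | None = None) -> list[Contour]:
        out = self.contours
        if phase is not None:
            out = [c for c in out if c.phase == phase]
        if structure is not None:
            out = [c for c in out if c.structure == structure]
        return list(out)


# ---------------------------------------------------------------------------
# cine stack I/O


def write_cine(stack: CineStack, path: str | Path) -> None:
    """Write a :class:`CineStack` as NIfTI-1 plus a ``*.meta.json`` sidecar.

    File axes are ``(col, row, slice, phase)`` so that spatial axes come
    first, as NIfTI expects; :func:`read_cine` restores the package's
    ``(phase, slice, row, col)`` order.
    """
    path = Path(path)
    data = np.transpose(stack.intensities, (3, 2, 1, 0))
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    row_mm, col_mm = stack.pixel_spacing_mm
    img.header.set_zooms((col_mm, row_mm, stack.effective_slice_thickness_mm, 1.0))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "slice_thickness_mm": stack.slice_thickness_mm,
                "interslice_gap_mm": stack.interslice_gap_mm,
            },
            indent=1,
        )
    )


def read_cine(path: str | Path) -> CineStack:
    """Read a cine stack from a 4D NIfTI file or a directory of 3D per-phase files.

    The NIfTI slice pixdim is interpreted as thickness + gap; the split is
    read from the sidecar JSON when present, otherwise the gap defaults to 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz")))
        if not files:
            raise ValueError(f"directory {path} contains no NIfTI files")
        volumes, zooms = [], None
        for f in files:
            img = nib.load(str(f))
            arr = np.asanyarray(img.dataobj)
            if arr.ndim != 3:
                raise ValueError(f"{f}: expected 3 dimensions per phase file, got {arr.ndim}")
            volumes.append(np.transpose(arr, (2, 1, 0)))  # -> (slice, row, col)
            zooms = img.header.get_zooms()[:3]
        data = np.stack(volumes, axis=0)
        sidecar = _sidecar_path(files[0])
    else:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 4:
            raise ValueError(f"expected 4 dimensions, got {arr.ndim}")
        data = np.transpose(arr, (3, 2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        sidecar = _sidecar_path(path)
    col_mm, row_mm, slice_mm = (float(z) for z in zooms)
    if slice_mm <= 0:
        raise ValueError(f"non-positive slice spacing in header: {slice_mm}")
    thickness, gap = slice_mm, 0.0
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        thickness = float(meta["slice_thickness_mm"])
        gap = float(meta["interslice_gap_mm"])
    return CineStack(
        intensities=data,
        pixel_spacing_mm=(row_mm, col_mm),
        slice_thickness_mm=thickness,
        interslice_gap_mm=gap,
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return path.with_name(name + _SIDECAR_SUFFIX)


# ---------------------------------------------------------------------------
# contour set I/O (JSON, schema version 1)


def write_contours(contour_set: ContourSet, path: str | Path) -> None:
    doc = {
        "version": 1,
        "pixel_spacing_mm": list(contour_set.pixel_spacing_mm),
        "slice_thickness_mm": contour_set.slice_thickness_mm,
        "interslice_gap_mm": contour_set.interslice_gap_mm,
        "contours": [
            {
                "phase": c.phase,
                "slice": c.slice,
                "structure": c.structure,
                "points": c.points.tolist(),
            }
            for c in contour_set.contours
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path: str | Path) -> ContourSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != 1:
        raise ValueError(f"unsupported contour file version: {doc.get('version')!r}")
    contours = [
        Contour(
            phase=int(c["phase"]),
            slice=int(c["slice"]),
            structure=str(c["structure"]),
            points=np.asarray(c["points"], dtype=float),
        )
        for c in doc["contours"]
    ]
    r, c = doc["pixel_spacing_mm"]
    return ContourSet(
        pixel_spacing_mm=(float(r), float(c)),
        slice_thickness_mm=float(doc["slice_thickness_mm"]),
        interslice_gap_mm=float(doc["interslice_gap_mm"]),
        contours=contours,
    )


# ---------------------------------------------------------------------------
# annotations I/O (JSON)


def write_annotations(ann: StudyAnnotations, path: str | Path) -> None:
    doc = {
        "ed_phase": ann.ed_phase,
        "es_phase": ann.es_phase,
        "ed": {"apical": ann.ed_apical_slice, "basal": ann.ed_basal_slice},
        "es": {"apical": ann.es_apical_slice, "basal": ann.es_basal_slice},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations(path: str | Path, stack: CineStack | None = None) -> StudyAnnotations:
    """Read annotations JSON; if ``stack`` is given, range-check against it."""
    doc = json.loads(Path(path).read_text())
    try:
        ann = StudyAnnotations(
            ed_phase=int(doc["ed_phase"]),
            es_phase=int(doc["es_phase"]),
            ed_apical_slice=int(doc["ed"]["apical"]),
            ed_basal_slice=int(doc["ed"]["basal"]),
            es_apical_slice=int(doc["es"]["apical"]),
            es_basal_slice=int(doc["es"]["basal"]),
        )
    except KeyError as exc:
        raise ValueError(f"annotations file {path} is missing field {exc}") from exc
    if stack is not None:
        ann.validate_against(stack)
    return ann
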