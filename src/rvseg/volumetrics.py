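"""Simpson's-rule ventricular volumes and ejection fraction.

Clinical Simpson's rule on a short-axis stack: the ventricular volume is the
sum over segmented slices of the contour area times the effective slice
thickness (slice thickness plus interslice gap),

    Volume = sum_i Area_i * Thickness_i

and the ejection fraction is EF = (EDV - ESV) / EDV * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Contour, ContourSet, StudyAnnotations

__all__ = [
    "SlicePlanimetry",
    "VolumeSet",
    "contour_area",
    "simpson_volume",
    "ejection_fraction",
    "volumes_from_contours",
]


@dataclass(frozen=True)
class SlicePlanimetry:
    """One slice's contribution to the Simpson sum."""

    slice_index: int
    area_mm2: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError(f"area must be >= 0, got {self.area_mm2}")
        if not self.thickness_mm > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness_mm}")


@dataclass(frozen=True)
class VolumeSet:
    """Per-phase ventricular volumes (mL) and the derived ejection fraction (%)."""

    ed_volume_ml: float
    es_volume_ml: float
    n_omitted_ed: int = 0
    n_omitted_es: int = 0

    @property
    def ef_percent(self) -> float:
        return ejection_fraction(self.ed_volume_ml, self.es_volume_ml)


def contour_area(contour: Contour, pixel_spacing_mm: tuple[float, float]) -> float:
    """Enclosed polygon area in mm² (shoelace × row_mm × col_mm, sign-free)."""
    row_mm, col_mm = pixel_spacing_mm
    return contour.area_px2() * row_mm * col_mm


def simpson_volume(planimetries: list[SlicePlanimetry]) -> float:
    """Σ Area_i · Thickness_i in mm³, returned in mL."""
    return sum(p.area_mm2 * p.thickness_mm for p in planimetries) / 1000.0


def ejection_fraction(ed_volume_ml: float, es_volume_ml: float) -> float:
    """EF = (EDV − ESV) / EDV × 100%."""
    if not ed_volume_ml > 0:
        raise ValueError(f"ED volume must be > 0, got {ed_volume_ml}")
    return (ed_volume_ml - es_volume_ml) / ed_volume_ml * 100.0

def phase_volume(
    contours: ContourSet,
    phase: int,
    structure: str = "rv_endo",
) -> tuple[float, int]:
    """Simpson volume (mL) of one phase's contours; also counts the slices present.

    Slices without a contour (omitted by propagation) contribute zero area.
    """
    planimetries = [
        SlicePlanimetry(
            slice_index=c.slice,
            area_mm2=contour_area(c, contours.pixel_spacing_mm),
            thickness_mm=contours.effective_slice_thickness_mm,
        )
        for c in contours.select(phase=phase, structure=structure)
    ]
    return simpson_volume(planimetries), len(planimetries)


def volumes_from_contours(
    contours: ContourSet,
    annotations: StudyAnnotations,
    structure: str = "rv_endo",
) -> VolumeSet:
    """ED/ES Simpson volumes and EF from a segmented contour set."""
    edv, n_ed = phase_volume(contours, annotations.ed_phase, structure)
    esv, n_es = phase_volume(contours, annotations.es_phase, structure)
    return VolumeSet(
        ed_volume_ml=edv,
        es_volume_ml=esv,
        n_omitted_ed=len(annotations.slices("ed")) - n_ed,
        n_omitted_es=len(annotations.slices("es")) - n_es,
    )
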