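"""End-to-end orchestration: phantom cohorts, segmentation runs, evaluation.

A single integer master seed is fanned out to per-subject / per-purpose
sub-seeds with a splitmix64-style derivation, so cohorts are reproducible
and extensible (adding a subject never changes the earlier ones).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .automaton import AutomatonConfig, optimize_seed
from .contour_metrics import pairwise_metrics
from .io_formats import CineStack, Contour, ContourSet, StudyAnnotations
from .phantom import PhantomDataset, PhantomSpec, generate_phantom, perturb_seed
from .propagation import PropagationConfig, propagate_phase
from .volumetrics import VolumeSet, volumes_from_contours

__all__ = [
    "derive_seed",
    "segment_study",
    "SubjectRun",
    "run_subject",
    "run_cohort",
    "CohortResult",
]

_SPLITMIX_GAMMA = 0x9E3779B97F4A7C15
_MASK64 = (1 << 64) - 1


def derive_seed(master: int, *path: int) -> int:
    """Derive a reproducible sub-seed (< 2^31) from a master seed and a path."""
    z = master & _MASK64
    for part in path:
        z = (z + _SPLITMIX_GAMMA + (part & _MASK64)) & _MASK64
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        z = z ^ (z >> 31)
    return z & 0x7FFFFFFF


def middle_slice(annotations: StudyAnnotations, phase: str | int) -> int:
    slices = annotations.slices(phase)
    return slices[len(slices) // 2]


def segment_study(
    stack: CineStack,
    annotations: StudyAnnotations,
    seeds: dict[int, tuple[Contour, int]],
    lv_contours: ContourSet | None = None,
    automaton_config: AutomatonConfig | None = None,
    propagation_config: PropagationConfig | None = None,
) -> ContourSet:
    """Segment each seeded phase and merge the per-phase contour sets.

    ``seeds`` maps a phase index to (rough seed contour, seed slice).
    """
    merged = ContourSet.from_stack(stack)
    for phase, (rough, seed_slice) in sorted(seeds.items()):
        opt = optimize_seed(
            stack.intensities[phase, seed_slice], rough, stack, phase, automaton_config
        )
        opt = replace(opt, phase=phase, slice=seed_slice)
        result = propagate_phase(
            stack,
            phase,
            annotations,
            opt,
            seed_slice,
            automaton_config,
            propagation_config,
            lv_contours,
        )
        for c in result.contours:
            merged.add(c)
        merged.warnings.extend(result.warnings)
    return merged


@dataclass
class SubjectRun:
    """One semi-automatic segmentation run of one phantom subject."""

    contours: ContourSet
    volumes: VolumeSet
    metrics: list[dict]  # per-slice dice / hausdorff vs truth


def run_subject(
    ds: PhantomDataset,
    run_seed: int,
    perturb_mm: float = 2.0,
    automaton_config: AutomatonConfig | None = None,
    propagation_config: PropagationConfig | None = None,
    attach_lv: bool = False,
) -> SubjectRun:
    """Segment ED and ES of one phantom subject from perturbed mid-slice seeds."""
    ann = ds.annotations
    seeds = {}
    for i, phase_name in enumerate(("ed", "es")):
        phase = ann.phase_index(phase_name)
        s = middle_slice(ann, phase_name)
        truth = ds.truth.get(phase, s, "rv_endo")
        rough = perturb_seed(
            truth, perturb_mm, derive_seed(run_seed, i), ds.stack.pixel_spacing_mm
        )
        seeds[phase] = (rough, s)
    lv = ds.truth if attach_lv else None
    contours = segment_study(
        ds.stack, ann, seeds, lv, automaton_config, propagation_config
    )
    volumes = volumes_from_contours(contours, ann)
    grid = ds.stack.intensities.shape[2:]
    metrics = pairwise_metrics(contours, ds.truth, grid)
    return SubjectRun(contours=contours, volumes=volumes, metrics=metrics)


@dataclass
class CohortResult:
    datasets: list[PhantomDataset]
    runs: list[list[SubjectRun]]  # runs[r][subject]

    def pooled_metrics(self, run: int, phase_of: str) -> dict[str, np.ndarray]:
        """Pool per-slice Dice/HD across subjects for one phase ('ed'/'es')."""
        dices, hds = [], []
        for ds, sr in zip(self.datasets, self.runs[run]):
            p = ds.annotations.phase_index(phase_of)
            for row in sr.metrics:
                if row["phase"] == p:
                    dices.append(row["dice"])
                    hds.append(row["hausdorff_mm"])
        return {"dice": np.array(dices), "hausdorff_mm": np.array(hds)}


def run_cohort(
    n_subjects: int,
    master_seed: int,
    base_spec: PhantomSpec | None = None,
    n_runs: int = 1,
    perturb_mm: float = 2.0,
    automaton_config: AutomatonConfig | None = None,
    propagation_config: PropagationConfig | None = None,
) -> CohortResult:
    """Generate a phantom cohort and segment it ``n_runs`` times per subject,
    each run with independently perturbed seed contours."""
    base = base_spec or PhantomSpec()
    datasets = [
        generate_phantom(replace(base, rng_seed=derive_seed(master_seed, 0, i)))
        for i in range(n_subjects)
    ]
    runs = []
    for r in range(n_runs):
        runs.append(
            [
                run_subject(
                    ds,
                    derive_seed(master_seed, 1, r, i),
                    perturb_mm,
                    automaton_config,
                    propagation_config,
                )
                for i, ds in enumerate(datasets)
            ]
        )
    return CohortResult(datasets=datasets, runs=runs)
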