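"""Shared fixtures: phantom datasets and a segmented synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from rvseg.phantom import PhantomSpec, generate_phantom
from rvseg.pipeline import run_cohort

COHORT_SEED = 42
COHORT_SUBJECTS = 10


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, shift-free phantom: every pixel is exactly one tissue level."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, shift_mm=0.0, rng_seed=1))


@pytest.fixture(scope="session")
def default_phantom():
    """Default-condition phantom: noise and per-slice shifts on."""
    return generate_phantom(PhantomSpec(rng_seed=1))


@pytest.fixture(scope="session")
def cohort():
    """Ten-subject default-condition cohort segmented twice with independently
    perturbed 2 mm seeds; shared by the benchmark tests."""
    return run_cohort(COHORT_SUBJECTS, COHORT_SEED, n_runs=2, perturb_mm=2.0)


def star_polygon(rng: np.random.Generator, center, r_min: float, r_max: float, n_vertices: int = 12):
    """Random star-shaped (hence simple) polygon around ``center``."""
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
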