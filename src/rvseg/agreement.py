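"""Validity and reproducibility statistics for paired ventricular measurements.

Implements the standard method-comparison toolkit: paired differences
summarized as median (IQR) and mean ± SD with Bland–Altman 95% limits of
agreement (mean ± 1.96·SD), the same in percentage terms relative to the
pair mean, a two-tailed Wilcoxon signed-rank test, and ordinary
least-squares regression with R².  ``run_protocol`` applies these to the
six-measurement design used in observer studies — two observers, the second
measuring twice, for both manual (M1, M2a, M2b) and semi-automatic
(A1, A2a, A2b) segmentation — yielding inter-/intra-observer variability
for each method plus the validity comparison A1 vs M1, for ED volume,
ES volume and ejection fraction.

Wilcoxon convention: zero differences are dropped, ties are mid-ranked, the
two-sided p-value is exact (full sign enumeration) for n ≤ 12 remaining
pairs and a normal approximation with tie and continuity corrections
otherwise; if every difference is zero, p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .volumetrics import VolumeSet

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "paired_diff_stats",
    "wilcoxon_signed_rank",
    "linear_fit",
    "run_protocol",
    "PROTOCOL_COMPARISONS",
]

EXACT_WILCOXON_MAX_N = 12

# the five analysis comparisons of the observer-study design
PROTOCOL_COMPARISONS = {
    "manual_interobserver": ("M1", "M2a"),
    "manual_intraobserver": ("M2a", "M2b"),
    "semiauto_interobserver": ("A1", "A2a"),
    "semiauto_intraobserver": ("A2a", "A2b"),
    "validity": ("A1", "M1"),
}

PARAMETERS = ("ed_volume_ml", "es_volume_ml", "ef_percent")


@dataclass(frozen=True)
class PairedMeasurements:
    """Two measurements of the same parameter on the same subjects."""

    subjects: tuple
    x: np.ndarray
    y: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
            raise ValueError("x and y must be equal-length non-empty 1D arrays")
        if len(self.subjects) != len(x):
            raise ValueError("subjects must align with the measurements")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @property
    def n(self) -> int:
        return len(self.x)

    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class AgreementReport:
    """Paired-difference summary in the layout of an observer-study table."""

    n: int
    units: str
    median_diff: float
    iqr_diff: tuple[float, float]  # 25th, 75th percentile
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]  # mean ± 1.96·SD
    median_pct: float
    iqr_pct: tuple[float, float]
    mean_pct: float
    sd_pct: float
    loa_pct: tuple[float, float]
    n_pct_excluded: int  # pairs with zero pair-mean (percentage undefined)
    bland_altman: np.ndarray  # (n, 2): (pair mean, difference)
    p_value: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "units": self.units,
            "median_diff": self.median_diff,
            "iqr_diff": list(self.iqr_diff),
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa": list(self.loa),
            "median_pct": self.median_pct,
            "iqr_pct": list(self.iqr_pct),
            "mean_pct": self.mean_pct,
            "sd_pct": self.sd_pct,
            "loa_pct": list(self.loa_pct),
            "n_pct_excluded": self.n_pct_excluded,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }
        return d


def _summary(values: np.ndarray) -> tuple[float, tuple[float, float], float, float, tuple[float, float]]:
    med = float(np.median(values))
    q25, q75 = (float(q) for q in np.percentile(values, [25, 75]))  # linear interpolation
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    loa = (mean - 1.96 * sd, mean + 1.96 * sd)
    return med, (q25, q75), mean, sd, loa


def paired_diff_stats(
    pm: PairedMeasurements,
    percentage_denominator: str = "pair_mean",
) -> AgreementReport:
    """Difference statistics d = x − y with Bland–Altman limits of agreement.

    Percentages are 100·d / denominator, where the denominator is the pair
    mean (x+y)/2 by default, or the reference measurement y when
    ``percentage_denominator="reference"`` (useful for validity analyses
    where y is the manual measurement).  Pairs with a zero denominator have
    an undefined percentage and are excluded from the percentage summaries,
    with a count reported.
    """
    if percentage_denominator not in ("pair_mean", "reference"):
        raise ValueError("percentage_denominator must be 'pair_mean' or 'reference'")
    d = pm.differences()
    med, iqr, mean, sd, loa = _summary(d)
    denom = (pm.x + pm.y) / 2.0 if percentage_denominator == "pair_mean" else pm.y
    ok = denom != 0
    pct = 100.0 * d[ok] / denom[ok]
    if pct.size:
        med_p, iqr_p, mean_p, sd_p, loa_p = _summary(pct)
    else:
        med_p, iqr_p, mean_p, sd_p, loa_p = np.nan, (np.nan, np.nan), np.nan, np.nan, (np.nan, np.nan)
    return AgreementReport(
        n=pm.n,
        units=pm.units,
        median_diff=med,
        iqr_diff=iqr,
        mean_diff=mean,
        sd_diff=sd,
        loa=loa,
        median_pct=med_p,
        iqr_pct=iqr_p,
        mean_pct=mean_p,
        sd_pct=sd_p,
        loa_pct=loa_p,
        n_pct_excluded=int((~ok).sum()),
        bland_altman=np.column_stack([(pm.x + pm.y) / 2.0, d]),
    )


def wilcoxon_signed_rank(pm: PairedMeasurements | Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on the paired differences."""
    d = pm.differences() if isinstance(pm, PairedMeasurements) else np.asarray(pm, dtype=float)
    d = d[d != 0]  # signed-rank convention: drop zero differences
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # mid-ranks on ties
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        # exact: enumerate all 2^n sign assignments of the observed |d| ranks
        stat_obs = min(w_pos, float(ranks[d < 0].sum()))
        count = 0
        for signs in product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            if min(w, ranks.sum() - w) <= stat_obs + 1e-12:
                count += 1
        return min(count / 2.0**n, 1.0)
    # normal approximation with tie correction and continuity correction
    mean_w = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean_w - 0.5 * np.sign(w_pos - mean_w)) / np.sqrt(var_w)
    return float(2.0 * stats.norm.sf(abs(z)))


def linear_fit(pm: PairedMeasurements) -> tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, R² = squared Pearson correlation)."""
    if pm.n < 2:
        raise ValueError("linear_fit needs n >= 2")
    if np.ptp(pm.x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(pm.y) == 0:
        return 0.0, float(pm.y[0]), 0.0
    res = stats.linregress(pm.x, pm.y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _full_report(pm: PairedMeasurements, percentage_denominator: str = "pair_mean") -> AgreementReport:
    report = paired_diff_stats(pm, percentage_denominator)
    report.p_value = wilcoxon_signed_rank(pm)
    if pm.n >= 2 and np.ptp(pm.x) > 0:
        report.slope, report.intercept, report.r_squared = linear_fit(pm)
    return report


def run_protocol(
    measurements: Mapping[str, Mapping[str, VolumeSet]],
    percentage_denominator: str = "pair_mean",
) -> dict[str, dict[str, AgreementReport]]:
    """Run the five-comparison observer protocol on six measurement tables.

    ``measurements`` maps each of M1, M2a, M2b, A1, A2a, A2b to a
    {subject: VolumeSet} table; all tables must cover the same subjects.
    Returns {comparison: {parameter: AgreementReport}} for ED volume,
    ES volume and EF.
    """
    missing = [k for k in {m for pair in PROTOCOL_COMPARISONS.values() for m in pair}
               if k not in measurements]
    if missing:
        raise ValueError(f"missing measurement tables: {sorted(missing)}")
    subjects = None
    for name, table in measurements.items():
        keys = tuple(sorted(table))
        if subjects is None:
            subjects = keys
        elif keys != subjects:
            raise ValueError(f"table {name} covers different subjects than the others")
    units = {"ed_volume_ml": "mL", "es_volume_ml": "mL", "ef_percent": "%"}
    out: dict[str, dict[str, AgreementReport]] = {}
    for comparison, (a, b) in PROTOCOL_COMPARISONS.items():
        out[comparison] = {}
        for param in PARAMETERS:
            x = np.array([getattr(measurements[a][s], param) for s in subjects])
            y = np.array([getattr(measurements[b][s], param) for s in subjects])
            pm = PairedMeasurements(subjects=subjects, x=x, y=y, units=units[param])
            out[comparison][param] = _full_report(pm, percentage_denominator)
    return out
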