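"""Study-level statistics: repeatability, paired challenge tests, BOLD timecourses.

Repeatability of a biomarker over paired same-session scans is summarised by
the within-subject coefficient of variation

    CoV = 100 * sqrt( (1/2N) * sum_i (d_i / m_i)^2 )

with d_i the paired difference and m_i the pair mean — the root-mean-square
pairwise form standard for test-retest imaging biomarkers.  Pre/post drug
comparisons of DWI medians use the two-sided Wilcoxon signed-rank test at 5%;
the repeated BOLD T2* measurements use a one-way repeated-measures ANOVA with
post-hoc paired comparisons against baseline ("a" flag) and against the
previous timepoint ("b" flag), gated on the omnibus test.  Agreement between
the perfusion-insensitive ADC and the IVIM tissue diffusion coefficient D is
quantified by Pearson correlation.

No multiple-testing correction is applied across parameters or regions, and
kidneys are treated as independent subjects (rat-level clustering is not
modelled); both choices are deliberate and reported with the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .presets import TIMEPOINT_LABELS

__all__ = [
    "PairedMeasurements",
    "TimecourseMeasurements",
    "PairedTestResult",
    "TimecourseTestResult",
    "CorrelationResult",
    "cov_repeatability",
    "paired_test",
    "bold_timecourse_test",
    "percent_change",
    "correlate_adc_d",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PairedMeasurements:
    """One kidney's paired values (scan 1 / scan 2, or pre / post) for one parameter."""

    unit_id: str
    parameter: str
    value_1: float
    value_2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value_1) and np.isfinite(self.value_2)):
            raise ValueError(f"{self.unit_id}/{self.parameter}: paired values must be finite")


@dataclass(frozen=True)
class TimecourseMeasurements:
    """One kidney's T2* baseline plus post-administration repeat values (ms)."""

    unit_id: str
    baseline: float
    post: tuple[float, ...]
    parameter: str = "t2_star"
    timepoint_labels: tuple[str, ...] = TIMEPOINT_LABELS

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline) or self.baseline <= 0:
            raise ValueError(f"{self.unit_id}: baseline must be finite and > 0")
        if len(self.post) != len(self.timepoint_labels):
            raise ValueError(
                f"{self.unit_id}: expected {len(self.timepoint_labels)} post values, got {len(self.post)}"
            )

    @property
    def series(self) -> tuple[float, ...]:
        return (self.baseline, *self.post)


def cov_repeatability(pairs: list[PairedMeasurements]) -> float:
    """Within-subject coefficient of variation (%) of paired repeat measurements.

    Pairs with non-positive mean are dropped with a warning; identical pairs
    give 0.  Invariant under rescaling all measurements and under swapping the
    two scans within any pair.
    """
    if not pairs:
        raise ValueError("cov_repeatability needs at least one pair")
    terms = []
    for p in pairs:
        mean = 0.5 * (p.value_1 + p.value_2)
        if mean <= 0:
            warnings.warn(f"dropping pair {p.unit_id}/{p.parameter}: non-positive mean", stacklevel=2)
            continue
        terms.append(((p.value_1 - p.value_2) / mean) ** 2)
    if not terms:
        raise ValueError("all pairs dropped (non-positive means); CoV undefined")
    return float(100.0 * np.sqrt(np.sum(terms) / (2 * len(terms))))


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    significant: bool
    note: str = ""


def paired_test(pairs: list[PairedMeasurements], alpha: float = ALPHA) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are removed (Wilcoxon's original convention); the exact
    null distribution is used for n <= 25 and the normal approximation with
    continuity correction above.  All-zero differences degenerate to p = 1.
    """
    if len(pairs) < 2:
        raise ValueError("paired_test needs at least 2 pairs")
    d = np.array([p.value_2 - p.value_1 for p in pairs], dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return PairedTestResult(
            statistic=0.0, p_value=1.0, n=len(d), significant=False,
            note="all paired differences are zero (degenerate)",
        )
    method = "exact" if nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size else "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided",
        correction=True, method=method,
    )
    p = float(res.pvalue)
    return PairedTestResult(
        statistic=float(res.statistic), p_value=p, n=len(d), significant=bool(p < alpha),
    )


@dataclass(frozen=True)
class TimecourseTestResult:
    """Omnibus RM-ANOVA outcome plus per-timepoint post-hoc flags.

    ``flags[label]`` contains "a" when the timepoint differs from baseline at
    p < alpha and "b" when it differs from the previous timepoint; post-hoc
    comparisons are only made when the omnibus test is significant.
    """

    omnibus_f: float
    omnibus_p: float
    n_units: int
    vs_baseline_p: dict[str, float]
    vs_previous_p: dict[str, float]
    flags: dict[str, str]
    notes: list[str] = field(default_factory=list)


def bold_timecourse_test(
    timecourses: list[TimecourseMeasurements],
    alpha: float = ALPHA,
) -> TimecourseTestResult:
    """One-way repeated-measures ANOVA across the T2* timecourse.

    Kidneys are the subject unit.  Units with incomplete timecourses are
    dropped with a warning.  When the omnibus p < alpha, paired t-tests flag
    each post timepoint against baseline ("a") and the previous timepoint ("b").
    """
    from statsmodels.stats.anova import AnovaRM

    complete = []
    notes = []
    for tc in timecourses:
        if all(np.isfinite(v) for v in tc.series):
            complete.append(tc)
        else:
            warnings.warn(f"dropping {tc.unit_id}: incomplete timecourse", stacklevel=2)
            notes.append(f"dropped {tc.unit_id}: incomplete timecourse")
    if len(complete) < 2:
        raise ValueError("bold_timecourse_test needs >= 2 units with complete timecourses")

    labels = ("baseline", *complete[0].timepoint_labels)
    values = np.array([tc.series for tc in complete])  # (units, timepoints)
    long = pd.DataFrame(
        {
            "unit": np.repeat([tc.unit_id for tc in complete], len(labels)),
            "time": list(labels) * len(complete),
            "value": values.ravel(),
        }
    )
    if np.allclose(values, values[:, [0]]):
        # constant within every unit: no timepoint effect, F degenerates to 0/0
        omnibus_f, omnibus_p = 0.0, 1.0
        notes.append("all timepoints identical within units (degenerate ANOVA)")
    else:
        table = AnovaRM(long, depvar="value", subject="unit", within=["time"]).fit().anova_table
        omnibus_f = float(table["F Value"].iloc[0])
        omnibus_p = float(table["Pr > F"].iloc[0])

    vs_baseline_p: dict[str, float] = {}
    vs_previous_p: dict[str, float] = {}
    flags = {label: "" for label in labels[1:]}
    if omnibus_p < alpha:
        for j, label in enumerate(labels[1:], start=1):
            pb = float(sps.ttest_rel(values[:, j], values[:, 0]).pvalue)
            pp = float(sps.ttest_rel(values[:, j], values[:, j - 1]).pvalue)
            vs_baseline_p[label] = pb
            vs_previous_p[label] = pp
            flags[label] = ("a" if pb < alpha else "") + ("b" if pp < alpha else "")
    return TimecourseTestResult(
        omnibus_f=omnibus_f, omnibus_p=omnibus_p, n_units=len(complete),
        vs_baseline_p=vs_baseline_p, vs_previous_p=vs_previous_p, flags=flags, notes=notes,
    )


def percent_change(timecourses: list[TimecourseMeasurements]) -> pd.DataFrame:
    """Percent-of-baseline T2* series per unit, with cohort mean +/- standard error.

    Returns a tidy frame with per-unit rows and a ``unit_id="cohort"`` summary
    row per timepoint (columns percent, sem).  The baseline timepoint is 100%
    identically.
    """
    if not timecourses:
        raise ValueError("percent_change needs at least one timecourse")
    rows = []
    labels = ("baseline", *timecourses[0].timepoint_labels)
    for tc in timecourses:
        for label, value in zip(labels, tc.series):
            rows.append(
                {"unit_id": tc.unit_id, "timepoint": label,
                 "percent": 100.0 * value / tc.baseline}
            )
    per_unit = pd.DataFrame(rows)
    cohort = (
        per_unit.groupby("timepoint", sort=False)["percent"]
        .agg(percent="mean", sem=lambda s: s.sem(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    cohort.insert(0, "unit_id", "cohort")
    return pd.concat([per_unit, cohort], ignore_index=True)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool = True
    note: str = ""


def correlate_adc_d(adc_values, d_values) -> CorrelationResult:
    """Pearson correlation between paired ADC and D region medians.

    With fewer than 3 pairs the call is rejected; zero variance in either
    vector makes r undefined and is reported as such rather than raising.
    """
    adc = np.asarray(adc_values, float)
    d = np.asarray(d_values, float)
    if adc.shape != d.shape or adc.ndim != 1:
        raise ValueError("adc_values and d_values must be 1-D and the same length")
    if adc.size < 3:
        raise ValueError("correlate_adc_d needs at least 3 paired values")
    if np.std(adc) == 0 or np.std(d) == 0:
        return CorrelationResult(
            r=np.nan, p_value=np.nan, n=adc.size, defined=False,
            note="zero variance in one input; correlation undefined",
        )
    res = sps.pearsonr(adc, d)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=adc.size)
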