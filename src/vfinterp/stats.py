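"""Nonparametric comparison of interpolators and subject groups.

Paired one-tailed Wilcoxon signed-rank tests ask whether a reference
interpolator is significantly better than each competitor; unpaired
two-tailed Wilcoxon rank-sum (Mann-Whitney) tests ask whether a metric
differs between the normal and patient groups.  Multiple comparisons across
the nine interpolators are Bonferroni-corrected (0.05 / 9 ~= 0.0055).

"Better" is metric-specific: smaller for MAE, RMSE, TV1 and TV2; larger for
Willmott's d1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, PairingError

__all__ = [
    "TestResult",
    "MetricRecord",
    "ComparisonTable",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bonferroni_alpha",
    "build_comparison_tables",
    "build_group_difference_table",
    "METRIC_DIRECTION",
    "records_to_frame",
]

#: +1 means larger is better, -1 means smaller is better
METRIC_DIRECTION: dict[str, int] = {"mae": -1, "rmse": -1, "d1": +1, "tv1": -1, "tv2": -1}

_EXACT_N = 25  # exact signed-rank null up to this many nonzero differences


@dataclass(frozen=True)
class TestResult:
    p: float
    statistic: float
    exact: bool
    degenerate: bool = False  # all differences zero -> p = 1 by convention


@dataclass(frozen=True)
class MetricRecord:
    """Per-(examination, method) metric values feeding the comparison."""

    subject_id: str
    group: str
    eye: str
    replicate: int
    method: str
    mae: float = np.nan
    rmse: float = np.nan
    d1: float = np.nan
    tv1: float = np.nan
    tv2: float = np.nan
    fallback_count: int = 0

    @property
    def exam_key(self) -> tuple:
        return (self.subject_id, self.group, self.eye, self.replicate)


@dataclass
class ComparisonTable:
    """Means plus one-tailed p-values of a reference method vs. the others.

    ``pvalues[m]`` is present only where the reference had the better mean
    (the one-tailed convention); ``flags[m]`` marks significance at the
    Bonferroni-corrected level.
    """

    metric: str
    scope: str                       # overall | normal | patient
    reference: str
    means: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)
    alpha_corrected: float = 0.05 / 9


def wilcoxon_signed_rank(
    paired_a, paired_b, tail: str = "one_sided_a_better"
) -> TestResult:
    """Paired signed-rank test on a - b; zero differences are dropped.

    ``one_sided_a_better`` tests H1: a has *smaller* values than b (callers
    negate d1-like metrics first).  Exact null distribution when <= 25
    nonzero untied differences; otherwise a tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(p=1.0, statistic=0.0, exact=True, degenerate=True)
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= _EXACT_N and not ties) else "approx"
    alternative = "less" if tail == "one_sided_a_better" else "two-sided"
    res = sps.wilcoxon(
        d, zero_method="wilcox", alternative=alternative, method=method,
        correction=(method == "approx"),
    )
    return TestResult(p=float(res.pvalue), statistic=float(res.statistic), exact=method == "exact")


def wilcoxon_rank_sum(sample_a, sample_b) -> TestResult:
    """Two-tailed rank-sum (Mann-Whitney U) test with midranks for ties.

    Exact for small untied samples, tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not ties and a.size + b.size <= 40) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=method == "asymptotic"
    )
    return TestResult(
        p=float(min(res.pvalue, 1.0)), statistic=float(res.statistic), exact=method == "exact"
    )


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 9) -> float:
    """Bonferroni-corrected significance level alpha / n (0.05/9 ~= 0.0055)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def records_to_frame(records) -> pd.DataFrame:
    """Normalize MetricRecords (or an equivalent DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def _paired_matrix(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["subject_id", "group", "eye", "replicate"],
        columns="method", values=metric, aggfunc="first",
    )
    bad = wide[wide.isna().any(axis=1)]
    if len(bad):
        raise PairingError(f"unpaired records for exams: {list(bad.index[:5])} ...")
    return wide


def build_comparison_tables(
    records,
    reference_method: str,
    metrics: tuple[str, ...] = ("mae", "rmse", "d1", "tv1", "tv2"),
    alpha: float = 0.05,
    n_comparisons: int = 9,
) -> list[ComparisonTable]:
    """Mean-metric and one-tailed p-value tables for each metric x scope.

    For every metric and scope (overall / normal / patient) the table holds
    each method's mean and, for methods against which the reference had the
    better mean, the one-tailed signed-rank p-value with a Bonferroni flag.
    """
    df = records_to_frame(records)
    metrics = tuple(m for m in metrics if m in df.columns and df[m].notna().any())
    alpha_c = bonferroni_alpha(alpha, n_comparisons)
    tables: list[ComparisonTable] = []
    for metric in metrics:
        wide_all = _paired_matrix(df, metric)
        if reference_method not in wide_all.columns:
            raise ValueError(f"reference method {reference_method!r} absent from records")
        direction = METRIC_DIRECTION.get(metric, -1)
        for scope in ("overall", "normal", "patient"):
            wide = (
                wide_all
                if scope == "overall"
                else wide_all[wide_all.index.get_level_values("group") == scope]
            )
            if len(wide) == 0:
                continue
            means = wide.mean().to_dict()
            table = ComparisonTable(
                metric=metric, scope=scope, reference=reference_method,
                means={m: float(v) for m, v in means.items()}, alpha_corrected=alpha_c,
            )
            ref_vals = wide[reference_method].to_numpy()
            for m in wide.columns:
                if m == reference_method:
                    continue
                ref_better = (
                    means[reference_method] < means[m]
                    if direction < 0
                    else means[reference_method] > means[m]
                )
                if not ref_better:
                    continue  # one-tailed convention: no p when mean is worse
                # orient so "a better" means "a smaller"
                a = ref_vals if direction < 0 else -ref_vals
                b = wide[m].to_numpy() if direction < 0 else -wide[m].to_numpy()
                res = wilcoxon_signed_rank(a, b, tail="one_sided_a_better")
                table.pvalues[m] = res.p
                table.flags[m] = bool(res.p < alpha_c)
            tables.append(table)
    return tables


def build_group_difference_table(
    records, metrics: tuple[str, ...] = ("mae", "rmse", "d1", "tv1", "tv2"), alpha: float = 0.05
) -> pd.DataFrame:
    """Two-tailed rank-sum p-values, normal vs patient, per metric x method."""
    df = records_to_frame(records)
    metrics = tuple(m for m in metrics if m in df.columns and df[m].notna().any())
    rows = []
    for metric in metrics:
        for method, sub in df.groupby("method"):
            a = sub.loc[sub.group == "normal", metric].dropna().to_numpy()
            b = sub.loc[sub.group == "patient", metric].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            res = wilcoxon_rank_sum(a, b)
            rows.append(
                {
                    "metric": metric, "method": method, "p": res.p,
                    "flag": bool(res.p < alpha),
                }
            )
    return pd.DataFrame(rows)
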