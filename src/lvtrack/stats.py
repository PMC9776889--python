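"""Cohort statistics: one-way ANOVA, Anderson-Darling normality, Pearson
correlation, and group summary tables.

The ANOVA is the classical between/within decomposition with the p-value
from the F(k-1, N-k) distribution.  The Anderson-Darling statistic uses the
case of estimated mean and variance with the small-sample correction
``A2* = A2 (1 + 4/n - 25/n^2)``, whose matching 5% critical value is 0.787
(the often-quoted 0.752 belongs to the alternative ``1 + 0.75/n + 2.25/n^2``
correction; mixing the two inflates the type-I error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError
from .imageio import ResultTable

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "NormalityResult",
    "one_way_anova",
    "anderson_darling",
    "pearson_r",
    "cohort_analysis",
    "CohortSummary",
    "AD_CRITICAL_5PCT",
]

AD_CRITICAL_5PCT = 0.787


@dataclass
class GroupedMeasurements:
    """Ordered mapping of group label -> 1D array of index values."""

    groups: dict

    def __post_init__(self) -> None:
        self.groups = {str(k): np.asarray(v, dtype=float)
                       for k, v in self.groups.items()}

    def validate_for_anova(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        for k, v in self.groups.items():
            if len(v) < 2:
                raise ValueError(f"group {k!r} needs at least 2 values")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: dict           # label -> (n, mean, sd)
    degenerate: bool = False


def one_way_anova(groups: GroupedMeasurements | dict) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Zero within-group variance with unequal means is degenerate (F infinite);
    it is reported as p = 0 with ``degenerate=True``.
    """
    if not isinstance(groups, GroupedMeasurements):
        groups = GroupedMeasurements(groups)
    groups.validate_for_anova()
    arrays = list(groups.groups.values())
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb, dfw = k - 1, n_total - k
    stats_out = {lab: (len(a), float(a.mean()), float(a.std(ddof=1)))
                 for lab, a in groups.groups.items()}
    if ssw <= 0:
        if ssb <= 0:
            return AnovaResult(0.0, dfb, dfw, 1.0, stats_out)
        return AnovaResult(float("inf"), dfb, dfw, 0.0, stats_out,
                           degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, p, stats_out)


@dataclass
class NormalityResult:
    a2: float
    a2_corrected: float
    reject_at_5pct: bool
    n: int


def anderson_darling(sample) -> NormalityResult:
    """Anderson-Darling test of normality with estimated mean and SD.

    A2 = -n - (1/n) sum_i (2i - 1) [ln F(z_(i)) + ln(1 - F(z_(n+1-i)))]
    with F the standard normal CDF of the standardised order statistics,
    corrected for sample size and compared to the matching 5% critical
    value (0.787).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("Anderson-Darling test needs n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise AnalysisError("zero-variance sample: normality test undefined")
    z = (x - x.mean()) / sd
    logcdf = sps.norm.logcdf(z)
    logsf = sps.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n
    a2c = a2 * (1.0 + 4.0 / n - 25.0 / n ** 2)
    return NormalityResult(float(a2), float(a2c),
                           bool(a2c > AD_CRITICAL_5PCT), n)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class CohortSummary:
    """Group summaries, tests and scatter data for a cohort result table.

    summary : per (index, group) mean/SD and box-plot quartiles
    tests   : per index the omnibus ANOVA plus unadjusted pairwise
              two-group ANOVAs, with per-group normality decisions
    scatter : one row per subject with its indices in columns (for EF vs
              torsion-correlation / peak-velocity scatter plots)
    notes   : warnings (missing values, skipped tests)
    """

    summary: pd.DataFrame
    tests: pd.DataFrame
    scatter: pd.DataFrame
    notes: list = field(default_factory=list)


def cohort_analysis(table: ResultTable) -> CohortSummary:
    df = table.to_frame()
    notes: list[str] = []
    indices = sorted(df["index"].unique())
    groups_all = sorted(df["group"].unique())

    summary_rows = []
    test_rows = []
    for index in indices:
        sub = df[df["index"] == index]
        by_group = {}
        for g in groups_all:
            vals = sub.loc[sub["group"] == g, "value"].to_numpy()
            if len(vals) == 0:
                notes.append(f"no {index} values in group {g}")
                continue
            by_group[g] = vals
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            summary_rows.append({
                "index": index, "group": g, "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "median": med, "q25": q25, "q75": q75,
            })
        eligible = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(eligible) < 2:
            notes.append(f"ANOVA skipped for {index}: fewer than 2 groups")
            continue
        normal = {}
        for g, v in eligible.items():
            if len(v) >= 8:
                normal[g] = not anderson_darling(v).reject_at_5pct
            else:
                normal[g] = None
        res = one_way_anova(eligible)
        test_rows.append({
            "index": index, "comparison": "omnibus",
            "F": res.F, "df_between": res.df_between,
            "df_within": res.df_within, "p": res.p,
            "normality": _fmt_normality(normal),
        })
        labs = sorted(eligible)
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                pw = one_way_anova({a: eligible[a], b: eligible[b]})
                test_rows.append({
                    "index": index, "comparison": f"{a}|{b}",
                    "F": pw.F, "df_between": pw.df_between,
                    "df_within": pw.df_within, "p": pw.p,
                    "normality": _fmt_normality(
                        {g: normal[g] for g in (a, b)}),
                })

    scatter = (df.pivot_table(index=["subject", "group"], columns="index",
                              values="value", aggfunc="first")
               .reset_index()
               .sort_values(["group", "subject"], kind="stable")
               .reset_index(drop=True))
    scatter.columns.name = None
    return CohortSummary(pd.DataFrame(summary_rows),
                         pd.DataFrame(test_rows), scatter, notes)


def _fmt_normality(normal: dict) -> str:
    parts = []
    for g, ok in normal.items():
        parts.append(f"{g}:{'normal' if ok else 'non-normal' if ok is not None else 'n<8'}")
    return ";".join(parts)
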