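"""Group statistics, survival and bookkeeping tables.

Comparisons between subtypes are gated on normality: if every group
passes the Shapiro-Wilk test at the gate alpha, a parametric test is
used (unpaired t for two groups, one-way ANOVA for more); otherwise the
rank-based counterpart (Mann-Whitney U / Kruskal-Wallis). Correlation is
Pearson's product-moment r. Survival is Kaplan-Meier with a two-group
log-rank test. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ComparisonResult",
    "SurvivalResult",
    "gated_compare",
    "pearson",
    "km_logrank",
    "subtype_fraction_table",
    "chi2_independence",
]


@dataclass
class ComparisonResult:
    variable: str
    groups: list[str]
    test: str  # 't' | 'mannwhitney' | 'anova' | 'kruskal'
    statistic: float
    pvalue: float
    group_means: dict[str, float]
    group_medians: dict[str, float]
    shapiro_pvalues: dict[str, float] = field(default_factory=dict)


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    statistic: float
    pvalue: float


def gated_compare(
    values,
    groups,
    alpha_normal: float = 0.05,
    variable: str = "",
) -> ComparisonResult:
    """Two-or-more-group comparison with a Shapiro-Wilk normality gate."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    split = {lab: values[groups == lab] for lab in labels}
    for lab, arr in split.items():
        if arr.size < 3:
            raise ValueError(f"group {lab!r} has n={arr.size} < 3")
    shapiro = {
        lab: (1.0 if np.ptp(arr) == 0 else float(stats.shapiro(arr).pvalue))
        for lab, arr in split.items()
    }
    normal = all(p >= alpha_normal for p in shapiro.values())
    arrays = [split[lab] for lab in labels]
    if len(labels) == 2:
        if np.ptp(values) == 0:
            test, statistic, p = ("t" if normal else "mannwhitney"), 0.0, 1.0
        elif normal:
            res = stats.ttest_ind(*arrays)
            test, statistic, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(*arrays, alternative="two-sided")
            test, statistic, p = "mannwhitney", float(res.statistic), float(res.pvalue)
    else:
        if normal:
            res = stats.f_oneway(*arrays)
            test, statistic, p = "anova", float(res.statistic), float(res.pvalue)
        else:
            res = stats.kruskal(*arrays)
            test, statistic, p = "kruskal", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        variable=variable,
        groups=labels,
        test=test,
        statistic=statistic,
        pvalue=float(np.clip(p, 0.0, 1.0)),
        group_means={lab: float(arr.mean()) for lab, arr in split.items()},
        group_medians={lab: float(np.median(arr)) for lab, arr in split.items()},
        shapiro_pvalues=shapiro,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    if times.size == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError(f"log-rank comparison requires exactly 2 groups, got {labels}")
    curves = {}
    for lab in labels:
        mask = groups == lab
        if not mask.any():
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        ev = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": ev["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    m0 = groups == labels[0]
    res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    return SurvivalResult(
        curves=curves, statistic=float(res.test_statistic), pvalue=float(res.p_value)
    )


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def subtype_fraction_table(calls_by_cohort: dict[str, pd.Series]) -> pd.DataFrame:
    """Counts and half-up-rounded percentages of tumor subtypes per cohort.

    ``calls_by_cohort`` maps cohort name to a per-tumor subtype Series
    (values 'A'/'B'). Percentages are rounded half-up to 2 decimals,
    matching the conventional rendering (48/87 -> 55.17).
    """
    rows = []
    for cohort, calls in calls_by_cohort.items():
        calls = pd.Series(calls)
        calls = calls[calls.isin(["A", "B"])]
        total = len(calls)
        for sub in ("A", "B"):
            count = int((calls == sub).sum())
            pct = _round_half_up(100.0 * count / total) if total else float("nan")
            rows.append(
                {"cohort": cohort, "subtype": sub, "n": total, "count": count,
                 "percent": pct}
            )
    return pd.DataFrame(rows)


def chi2_independence(labels_a, labels_b) -> tuple[float, float]:
    """Chi-square test of independence of two categorical labelings."""
    table = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
    res = stats.chi2_contingency(table.to_numpy())
    return float(res.statistic), float(res.pvalue)
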