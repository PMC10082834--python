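"""Longitudinal response metrics and group statistics.

Therapy response between sequential scans is expressed as percent change
from baseline,

    delta = 100 * (post - pre) / pre

for SUVmean, MTV and TLG, and classified EORTC-style on the SUV change:
above +25 % is progressive disease, below -15 % is partial response, and
everything between (boundaries included) is stable disease.

Cohort-level comparisons follow the conventional decision tree: test
each group for normality (Shapiro-Wilk) and the groups for homogeneity
of variance (Levene); if both pass, use a two-tailed unpaired t-test for
two groups or one-way ANOVA with Holm-Sidak-adjusted pairwise
comparisons for more; otherwise fall back to Kruskal-Wallis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pve import LesionMetrics

#: EORTC-style category bounds on delta-SUV (percent).
PROGRESSIVE_ABOVE_PCT = 25.0
PARTIAL_RESPONSE_BELOW_PCT = -15.0

ALPHA = 0.05


@dataclass(frozen=True)
class ResponseAssessment:
    delta_suv_pct: float
    delta_mtv_pct: float
    delta_tlg_pct: float
    category: str  # progressive | stable | partial_response


def delta_metric(pre: float, post: float) -> float:
    """Percent change from baseline: 100 * (post - pre) / pre."""
    if pre <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (post - pre) / pre


def classify_eortc(delta_suv_pct: float) -> str:
    """Map a percent SUV change to its response category.

    The published thresholds are strict on all three branches, leaving
    the exact boundary values unassigned; here +25 and -15 fall to
    ``stable`` (closed-interval convention).
    """
    if not math.isfinite(delta_suv_pct):
        raise ValueError("delta SUV must be finite")
    if delta_suv_pct > PROGRESSIVE_ABOVE_PCT:
        return "progressive"
    if delta_suv_pct < PARTIAL_RESPONSE_BELOW_PCT:
        return "partial_response"
    return "stable"


def assess(pre: LesionMetrics, post: LesionMetrics) -> ResponseAssessment:
    """Percent changes of SUVmean, MTV and TLG plus the EORTC category.

    The SUV change is computed on the same convention for both scans:
    corrected SUVmean when both scans carry a real correction, raw
    SUVmean otherwise, so a QC failure on one scan cannot masquerade as a
    metabolic change.
    """
    both_corrected = pre.rc_applied < 1.0 and post.rc_applied < 1.0
    if both_corrected:
        d_suv = delta_metric(pre.suv_mean_corrected, post.suv_mean_corrected)
    else:
        d_suv = delta_metric(pre.suv_mean, post.suv_mean)
    d_mtv = delta_metric(pre.mtv_mm3, post.mtv_mm3)
    d_tlg = delta_metric(pre.tlg, post.tlg)
    return ResponseAssessment(
        delta_suv_pct=d_suv,
        delta_mtv_pct=d_mtv,
        delta_tlg_pct=d_tlg,
        category=classify_eortc(d_suv),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Result of the cohort decision tree, naming the branch taken."""

    branch: str  # parametric | nonparametric
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    group_sizes: tuple[int, ...]
    normality_p: dict[str, Optional[float]]
    levene_p: Optional[float]
    pairwise_adjusted_p: Optional[dict[tuple[str, str], float]]
    alpha: float = ALPHA
    warnings: tuple[str, ...] = ()


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Compare a metric across treatment groups via the decision tree.

    ``table`` needs one row per animal with a ``group`` label column and
    the metric column.  Groups with fewer than 3 observations cannot be
    tested for normality, which sends the comparison down the
    nonparametric branch with a warning.
    """
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    if group_col not in table.columns:
        raise ValueError(f"group column {group_col!r} not in table")
    clean = table[[group_col, metric]].dropna()
    names = tuple(str(g) for g in pd.unique(clean[group_col]))
    samples = [np.asarray(clean.loc[clean[group_col] == g, metric], dtype=float) for g in names]
    sizes = tuple(len(s) for s in samples)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    if any(n < 2 for n in sizes):
        raise ValueError("each group needs at least two observations")

    notes: list[str] = []
    normality_p: dict[str, Optional[float]] = {}
    all_normal = True
    for g, s in zip(names, samples):
        if len(s) < 3:
            normality_p[g] = None
            all_normal = False
            notes.append(f"group {g!r} has <3 observations; normality untestable")
        elif np.ptp(s) == 0:
            normality_p[g] = None
            all_normal = False
            notes.append(f"group {g!r} is constant; normality untestable")
        else:
            p = float(stats.shapiro(s).pvalue)
            normality_p[g] = p
            all_normal &= p >= alpha

    levene_p: Optional[float] = None
    homogeneous = False
    if all_normal:
        levene_p = float(stats.levene(*samples).pvalue)
        homogeneous = levene_p >= alpha

    pairwise = None
    if all_normal and homogeneous:
        branch = "parametric"
        if len(names) == 2:
            res = stats.ttest_ind(samples[0], samples[1])
            test_name = "two-tailed unpaired t-test"
        else:
            res = stats.f_oneway(*samples)
            test_name = "one-way ANOVA + Holm-Sidak pairwise"
            pairs = list(combinations(range(len(names)), 2))
            raw = [float(stats.ttest_ind(samples[i], samples[j]).pvalue) for i, j in pairs]
            adj = multipletests(raw, alpha=alpha, method="holm-sidak")[1]
            pairwise = {(names[i], names[j]): float(p) for (i, j), p in zip(pairs, adj)}
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        branch = "nonparametric"
        test_name = "Kruskal-Wallis"
        res = stats.kruskal(*samples)
        statistic, p_value = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        branch=branch,
        test_name=test_name,
        statistic=statistic,
        p_value=p_value,
        groups=names,
        group_sizes=sizes,
        normality_p=normality_p,
        levene_p=levene_p,
        pairwise_adjusted_p=pairwise,
        alpha=alpha,
        warnings=tuple(notes),
    )
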