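"""Normality-dispatched group comparisons, Spearman correlation and
empirical ROC/AUC biomarker evaluation.

Dispatch rule: every group must pass Shapiro-Wilk at alpha for the
parametric branch (t-test for two groups, one-way ANOVA with Tukey HSD for
more); otherwise the nonparametric branch is used (Mann-Whitney for two
groups, Kruskal-Wallis omnibus with Bonferroni-adjusted Dunn pairwise
comparisons for more).  Significance codes follow the star convention:
``*`` P < 0.05, ``**`` P < 0.01, ``***`` P < 0.001.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    groups: dict[str, int]  # label -> n
    test_used: str  # t_test | mann_whitney | anova_tukey | kruskal_wallis_dunn
    normality_p: dict[str, Optional[float]]
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    significance_code: dict[tuple[str, str], str]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    flag: str = "ok"


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_class: object


def significance_code(p: float) -> str:
    """Star code at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def shapiro_wilk(values: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value; a constant vector is reported as
    non-normal (p = 0)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def _dunn_pairwise(
    samples: Mapping[str, np.ndarray], labels: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Dunn's test on pooled ranks with tie correction, Bonferroni-adjusted."""
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # mean rank per group
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        n_g = samples[g].size
        mean_rank[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / samples[a].size + 1.0 / samples[b].size))
        if se == 0:
            p = 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * n_pairs)
    return out


def compare_groups(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparisonResult:
    """Normality-dispatched comparison of two or more groups.

    All groups normal by Shapiro-Wilk at ``alpha`` -> unpaired two-tailed
    t-test (2 groups) or one-way ANOVA with Tukey HSD pairwise (>2); any
    group non-normal -> Mann-Whitney (2) or Kruskal-Wallis with Dunn
    pairwise, Bonferroni-adjusted (>2).
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("compare_groups requires at least 2 groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in labels}
    for g, x in arrays.items():
        if x.size < 3:
            raise ValueError(f"group {g!r} has n={x.size} < 3")

    normality = {g: shapiro_wilk(x) for g, x in arrays.items()}
    all_normal = all(p > alpha for p in normality.values())

    pairwise: dict[tuple[str, str], float] = {}
    if len(labels) == 2:
        a, b = labels
        if all_normal:
            test_used = "t_test"
            p = float(sps.ttest_ind(arrays[a], arrays[b]).pvalue)
        else:
            test_used = "mann_whitney"
            p = float(
                sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue
            )
        omnibus_p = p
        pairwise[(a, b)] = p
    else:
        if all_normal:
            test_used = "anova_tukey"
            omnibus_p = float(sps.f_oneway(*(arrays[g] for g in labels)).pvalue)
            tukey = sps.tukey_hsd(*(arrays[g] for g in labels))
            for i, j in itertools.combinations(range(len(labels)), 2):
                pairwise[(labels[i], labels[j])] = float(tukey.pvalue[i, j])
        else:
            test_used = "kruskal_wallis_dunn"
            omnibus_p = float(sps.kruskal(*(arrays[g] for g in labels)).pvalue)
            pairwise = _dunn_pairwise(arrays, labels)

    if math.isnan(omnibus_p):  # identical constant groups
        omnibus_p = 1.0
        pairwise = {k: 1.0 for k in pairwise}

    return GroupComparisonResult(
        groups={g: int(arrays[g].size) for g in labels},
        test_used=test_used,
        normality_p=normality,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise,
        significance_code={
            k: significance_code(p) for k, p in pairwise.items()
        },
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties; large-sample p.

    A zero-variance argument after ranking yields an undefined rho,
    returned as NaN with flag ``"undefined"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            rho=float("nan"), p_value=float("nan"), n=int(x.size), flag="undefined"
        )
    res = sps.spearmanr(x, y)
    return CorrelationResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=int(x.size)
    )


def roc_auc(
    values: Sequence[float], labels: Sequence[object], positive_class: object
) -> ROCResult:
    """Empirical ROC over all observed thresholds; higher value = more
    likely positive.

    AUC equals the Mann-Whitney probability U/(n1*n0) with ties counted as
    1/2.  Orientation is fixed by ``positive_class``: an AUC below 0.5 is
    reported as-is, never flipped.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([lab == positive_class for lab in labels], dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")

    # AUC via mid-ranks (ties count 1/2)
    ranks = sps.rankdata(v)
    auc = (float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # empirical curve: predict positive iff value >= threshold
    thresholds = np.concatenate(([np.inf], np.unique(v)[::-1]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = v >= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        positive_class=positive_class,
    )


@dataclass
class _Provenance:
    """Serializable provenance of one statistics call (for run logs)."""

    operation: str
    details: dict = field(default_factory=dict)


def comparison_to_dict(res: GroupComparisonResult) -> dict:
    """JSON-friendly rendering of a group comparison."""
    return {
        "groups": res.groups,
        "test_used": res.test_used,
        "normality_p": res.normality_p,
        "omnibus_p": res.omnibus_p,
        "pairwise": [
            {
                "group_a": a,
                "group_b": b,
                "p": res.pairwise_p[(a, b)],
                "code": res.significance_code[(a, b)],
            }
            for (a, b) in res.pairwise_p
        ],
    }
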