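"""Discrimination: AUC with DeLong variance, and paired/unpaired AUC tests.

The AUC is the Mann-Whitney concordance probability (ties count 1/2).  Its
variance — and, for two models evaluated on the same subjects, the covariance
of the two AUCs — comes from the structural-components (DeLong) estimator,
computed with the midrank algorithm so it runs in O(n log n).  Two AUCs are
compared with z = (A1 - A2) / SE(A1 - A2); the squared statistic is referred
to a chi-square distribution with 1 df (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedAUCError",
    "AUCEstimate",
    "AUCComparison",
    "compute_auc",
    "compare_auc",
    "compare_auc_paired",
    "compare_auc_unpaired",
    "delong_components",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined: the labels contain only one class."""


@dataclass
class AUCEstimate:
    model: str
    outcome: str
    n: int
    n_events: int
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class AUCComparison:
    auc_a: AUCEstimate
    auc_b: AUCEstimate
    statistic: float   # z^2, chi-square with 1 df
    p_value: float
    paired: bool


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based; ties get the average rank)."""
    return stats.rankdata(x, method="average")


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError(
            f"need at least one event and one non-event (got {len(pos)} events, "
            f"{len(neg)} non-events)")
    return pos, neg


def delong_components(scores, labels):
    """AUC and per-subject structural components ``(auc, v_events, v_nonevents)``.

    ``v_events[i]`` is the proportion of non-events the i-th event outranks
    (ties 1/2); ``v_nonevents[j]`` the proportion of events the j-th non-event
    is outranked by.  Both have mean equal to the AUC.
    """
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    v_events = (tz[:m] - tx) / n
    v_nonevents = 1.0 - (tz[m:] - ty) / m
    auc = float(tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n))
    return auc, v_events, v_nonevents


def _delong_variance(v_events, v_nonevents) -> float:
    m, n = len(v_events), len(v_nonevents)
    s01 = np.var(v_events, ddof=1) if m > 1 else 0.0
    s10 = np.var(v_nonevents, ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


def compute_auc(
    scores,
    labels,
    model: str = "",
    outcome: str = "",
    alpha: float = 0.05,
) -> AUCEstimate:
    """AUC with a DeLong standard error and Wald CI (clipped to [0, 1])."""
    auc, v01, v10 = delong_components(scores, labels)
    se = float(np.sqrt(_delong_variance(v01, v10)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AUCEstimate(
        model=model,
        outcome=outcome,
        n=len(v01) + len(v10),
        n_events=len(v01),
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
    )


def _chi2_from_diff(diff: float, var: float):
    if var <= 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    statistic = diff * diff / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def compare_auc_paired(scores_a, scores_b, labels,
                       model_a: str = "a", model_b: str = "b",
                       outcome: str = "") -> AUCComparison:
    """DeLong test for two models scored on the same subjects."""
    auc_a, va01, va10 = delong_components(scores_a, labels)
    auc_b, vb01, vb10 = delong_components(scores_b, labels)
    m, n = len(va01), len(va10)
    var_a = _delong_variance(va01, va10)
    var_b = _delong_variance(vb01, vb10)
    cov = 0.0
    if m > 1:
        cov += np.cov(va01, vb01, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(va10, vb10, ddof=1)[0, 1] / n
    statistic, p = _chi2_from_diff(auc_a - auc_b, var_a + var_b - 2.0 * cov)
    est_a = compute_auc(scores_a, labels, model=model_a, outcome=outcome)
    est_b = compute_auc(scores_b, labels, model=model_b, outcome=outcome)
    return AUCComparison(est_a, est_b, statistic, p, paired=True)


def compare_auc_unpaired(
    a: AUCEstimate,
    b: AUCEstimate,
    ids_a=None,
    ids_b=None,
) -> AUCComparison:
    """Chi-square test of AUC equality for two independent subgroups.

    Pass the subgroup id sets to assert disjointness: overlapping subgroups
    violate the independence assumption and raise ``ValueError``.
    """
    if ids_a is not None and ids_b is not None:
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise ValueError(
                f"unpaired comparison requires disjoint subgroups; "
                f"{len(overlap)} shared subject(s)")
    statistic, p = _chi2_from_diff(a.auc - b.auc, a.se**2 + b.se**2)
    return AUCComparison(a, b, statistic, p, paired=False)


def compare_auc(a, b, labels=None, **kwargs) -> AUCComparison:
    """Dispatch: AUCEstimate pair -> unpaired test; score vectors + shared
    labels -> paired DeLong test."""
    if isinstance(a, AUCEstimate) and isinstance(b, AUCEstimate):
        return compare_auc_unpaired(a, b, **kwargs)
    if labels is None:
        raise ValueError("paired comparison needs the shared outcome labels")
    return compare_auc_paired(a, b, labels, **kwargs)
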