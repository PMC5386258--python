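"""Mann-Whitney AUC, DeLong variance, and confidence intervals.

The AUC of a probabilistic classifier equals the Mann-Whitney two-sample
statistic: the probability that a randomly chosen positive (treatment
success) receives a higher score than a randomly chosen negative, with
ties counted one half.  DeLong's method estimates the sampling variance of
this statistic nonparametrically from per-observation "structural
components" and yields asymptotic normal confidence intervals.

All functions take a score vector and a binary label vector; labels are
coerced with 1 = positive.  Ties are handled with midranks throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "AUCEstimate",
    "auc_mann_whitney",
    "delong_variance",
    "auc_confint",
    "relative_improvement",
    "variance_excess",
]


@dataclass(frozen=True)
class AUCEstimate:
    """AUC point estimate with DeLong variance and a normal-theory CI."""

    auc: float
    variance: float
    ci: tuple[float, float]
    level: float

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("point estimate outside its confidence interval")


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    y = labels.astype(bool) if labels.dtype == bool else (np.asarray(labels, dtype=float) == 1)
    pos = scores[y]
    neg = scores[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """Tie-aware AUC via midranks in O((m+n) log(m+n)).

    Equals (1/mn) sum_ij psi(X_i, Y_j) where psi is 1 when a positive
    outscores a negative, 1/2 on a tie, 0 otherwise.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong components V10 (per positive) and V01 (per negative).

    V10_i = (1/n) sum_j psi(X_i, Y_j);  V01_j = (1/m) sum_i psi(X_i, Y_j).
    Computed from midranks: combined minus within-group midrank counts,
    for each positive, the negatives it beats (ties at half weight).
    """
    m, n = pos.size, neg.size
    rank_all = rankdata(np.concatenate([pos, neg]))
    rank_pos = rankdata(pos)
    rank_neg = rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance of the Mann-Whitney AUC: S10/m + S01/n.

    S10 and S01 are the sample variances (denominators m-1, n-1) of the
    structural components; requires at least two observations per class.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance requires >= 2 positives and >= 2 negatives")
    v10, v01 = _structural_components(pos, neg)
    return float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)


def auc_confint(scores, labels, level: float = 0.95) -> AUCEstimate:
    """AUC with DeLong variance and a Wald CI truncated to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    auc = auc_mann_whitney(scores, labels)
    var = delong_variance(scores, labels)
    z = norm.ppf(0.5 * (1.0 + level))
    half = z * math.sqrt(var)
    lo = max(0.0, auc - half)
    hi = min(1.0, auc + half)
    return AUCEstimate(auc=auc, variance=var, ci=(lo, hi), level=level)


def relative_improvement(aucs) -> float:
    """Percent spread of a set of AUCs: 100 * (max - min) / max, 1 decimal.

    With the best model as reference, this is the relative gain of the best
    over the worst method in the comparison.
    """
    values = np.asarray(list(aucs), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one AUC")
    if values.size < 2:
        return 0.0
    best = values.max()
    return round(100.0 * (best - values.min()) / best, 1)


def variance_excess(variances: dict[str, float], reference: str) -> int:
    """Largest percent excess of any model's AUC variance over a reference.

    100 * (max variance / reference variance - 1), rounded to the nearest
    integer, e.g. how much larger the worst competitor's DeLong variance is
    than the super learner's.
    """
    if reference not in variances:
        raise KeyError(f"reference label {reference!r} not present")
    ref = float(variances[reference])
    if ref <= 0.0:
        raise ValueError("reference variance must be positive")
    worst = max(float(v) for v in variances.values())
    return int(round(100.0 * (worst / ref - 1.0)))
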