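"""Closed-form statistics used throughout the pipeline.

Classification metrics (accuracy / precision / recall / MCC) from confusion
counts, empirical Monte-Carlo p-values, the normal-approximated Wilcoxon
rank-sum test, Spearman rank correlation, and Barnard's unconditional exact
test for 2x2 tables.

Conventions that matter for reproducibility:

* precision / recall with a zero denominator are *undefined* (NaN + flag),
  which is distinct from 0;
* MCC with any zero denominator factor is 0 by convention, flagged;
* the Wilcoxon z uses mid-ranks, tie-corrected variance and a continuity
  correction, matching the approximate method of the common commercial
  statistics environments;
* Barnard's test maximizes the tail probability over a grid of the common
  success probability, with a pooled-variance (Wald) score statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "confusion_metrics",
    "mcc",
    "empirical_p",
    "wilcoxon_ranksum",
    "spearman",
    "barnard_exact",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN cell counts of a binary confusion matrix."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall / MCC with undefined-denominator flags.

    ``precision`` and ``recall`` are NaN when their denominator is zero
    (all-negative predictions, no positive cases); ``mcc`` is 0 by
    convention whenever a denominator factor vanishes.  The corresponding
    ``*_defined`` flag records whether the value came from a well-posed
    ratio.
    """

    accuracy: float
    precision: float
    recall: float
    mcc: float
    precision_defined: bool = True
    recall_defined: bool = True
    mcc_defined: bool = True


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts treating label 1 (or True) as the positive class."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
    )


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """accuracy = (TP+TN)/all, precision = TP/(TP+FP), recall = TP/(TP+FN)."""
    acc = (c.tp + c.tn) / c.total
    p_den = c.tp + c.fp
    r_den = c.tp + c.fn
    precision = c.tp / p_den if p_den else math.nan
    recall = c.tp / r_den if r_den else math.nan
    m, m_def = _mcc_value(c)
    return MetricsReport(
        accuracy=acc,
        precision=precision,
        recall=recall,
        mcc=m,
        precision_defined=p_den > 0,
        recall_defined=r_den > 0,
        mcc_defined=m_def,
    )


def _mcc_value(c: ConfusionCounts) -> tuple[float, bool]:
    factors = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if any(f == 0 for f in factors):
        return 0.0, False
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(math.prod(float(f) for f in factors)), True


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (flagged via report) if degenerate."""
    return _mcc_value(c)[0]


def empirical_p(r: int, n: int) -> float:
    """Monte-Carlo empirical p-value (r + 1) / (n + 1).

    ``r`` is the number of null samples at or above the observed statistic
    over ``n`` permutations.  The floor is 1/(n+1): 0.001 (to three
    decimals) at n = 1000 even when no null sample reaches the observed
    value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= r <= n:
        raise ValueError(f"r must be in [0, n], got r={r}, n={n}")
    return (r + 1) / (n + 1)


def wilcoxon_ranksum(
    x,
    y,
    *,
    continuity: bool = True,
    tie_correction: bool = True,
) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test with normal approximation.

    Returns ``(z, p)`` where ``z`` is the standardized rank-sum of the
    first sample (mid-ranks for ties, tie-corrected variance, continuity
    correction by default) and ``p = 2 * (1 - Phi(|z|))``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = _sps.rankdata(np.concatenate([x, y]))
    w = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2.0
    var_w = nx * ny * (n + 1) / 12.0
    if tie_correction:
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        ties = counts[counts > 1]
        if ties.size and n > 1:
            var_w -= nx * ny * np.sum(ties**3 - ties) / (12.0 * n * (n - 1))
    if var_w <= 0:
        # all observations identical: no evidence either way
        return 0.0, 1.0
    diff = w - mean_w
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / math.sqrt(var_w)
    p = 2.0 * _sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with two-tailed t-approximation.

    Returns ``(rho, p)`` with ``p`` from the t distribution on n - 2
    degrees of freedom.  Constant input makes rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)


def _wald_score(x1: np.ndarray, x2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pooled-variance score statistic for difference of two proportions."""
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p1 - p2) / np.sqrt(var)
    return np.where(var > 0, t, 0.0)


def barnard_exact(table, *, grid_step: float = 1e-3) -> float:
    """Barnard's unconditional exact test for a 2x2 table, two-sided.

    ``table`` is ``[[a, b], [c, d]]`` with *columns* as the two groups
    (column totals are the fixed group sizes).  The p-value is the maximum
    over a grid of the common success probability pi of the probability,
    under independent binomials, of all outcome tables whose absolute
    pooled-score statistic is at least the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    n1, n2 = a + c, b + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both group sizes must be positive")
    return _barnard_cached(a, b, n1, n2, float(grid_step))


@lru_cache(maxsize=100_000)
def _barnard_cached(x1_obs: int, x2_obs: int, n1: int, n2: int, grid_step: float) -> float:
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    t_all = _wald_score(x1[:, None], x2[None, :], n1, n2)
    t_obs = abs(_wald_score(np.array([x1_obs]), np.array([x2_obs]), n1, n2)[0])
    # numerical tolerance so equal-statistic tables fall in the tail
    tail = np.abs(t_all) >= t_obs - 1e-10
    if tail.all():
        return 1.0
    pis = np.arange(grid_step, 1.0, grid_step)
    best = 0.0
    for pi in pis:
        pmf1 = _sps.binom.pmf(x1, n1, pi)
        pmf2 = _sps.binom.pmf(x2, n2, pi)
        prob = pmf1[:, None] * pmf2[None, :]
        best = max(best, float(prob[tail].sum()))
    return min(best, 1.0)
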