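"""Monte-Carlo permutation tests for classifier metrics and the ROI screen.

Significance of an out-of-fold metric is assessed by scrambling the labels
and re-running the *full* nested-CV pipeline — feature selection, class
weights and C-tuning included — on each permutation, then comparing the
observed metric against the null distribution with the conservative
empirical p-value (r + 1)/(n + 1), where r counts null samples at or above
the observed value.

The regional lesion screen is two-stage: a cheap 100-iteration permutation
screen on MCC selects candidate ROIs (p < 0.05), which then receive a
1000-iteration test on MCC, accuracy, precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import ml_engine, stats_core

__all__ = [
    "PermutationResult",
    "RoiScreenResult",
    "permute_labels",
    "permutation_null",
    "two_stage_screen",
]

_METRICS = ("accuracy", "precision", "recall", "mcc")


@dataclass(frozen=True)
class PermutationResult:
    """Observed metric, its permutation null and the empirical p-value."""

    metric: str
    observed: float
    null: np.ndarray  # length n_iter; NaN where the metric was undefined
    seed: int

    @property
    def n(self) -> int:
        """Number of valid (defined) null samples."""
        return int(np.sum(~np.isnan(self.null)))

    @property
    def r(self) -> int:
        """Null samples at or above the observed value."""
        valid = self.null[~np.isnan(self.null)]
        return int(np.sum(valid >= self.observed))

    @property
    def p(self) -> float:
        return stats_core.empirical_p(self.r, self.n)


@dataclass(frozen=True)
class RoiScreenResult:
    """Two-stage screen outcome for one ROI-level lesion-presence model."""

    roi: int
    observed_mcc: float
    stage1_p: float
    candidate: bool
    stage2: Mapping[str, PermutationResult] | None  # None if not a candidate

    @property
    def significant(self) -> bool:
        """Significant on all four metrics in stage 2."""
        if self.stage2 is None:
            return False
        return all(res.p < 0.05 for res in self.stage2.values())


def permute_labels(y, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the label vector (counts preserved)."""
    y = np.asarray(y)
    return y[rng.permutation(len(y))]


def permutation_null(
    X,
    y,
    config: ml_engine.CVConfig,
    metrics: Sequence[str] = ("accuracy", "precision", "recall"),
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict[str, PermutationResult]:
    """Permutation null for nested-CV metrics; one result per metric.

    Each iteration permutes the labels with a derived seed (base seed +
    iteration index), re-runs the nested CV against the permuted labels
    and scores the out-of-fold predictions against those same permuted
    labels.  Undefined metrics (e.g. precision when a permutation yields
    no positive predictions) are stored as NaN and excluded from both the
    null mean and the empirical p count.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for m in metrics:
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}")
    base_seed = config.seed if seed is None else seed
    y = np.asarray(y).astype(int)
    observed_pv = ml_engine.nested_cv_predict(X, y, config)
    observed = ml_engine.evaluate_predictions(y, observed_pv.predictions)
    null = {m: np.empty(n_iter) for m in metrics}
    for it in range(n_iter):
        rng = np.random.default_rng((base_seed + 1 + it) % (2**31 - 1))
        y_perm = permute_labels(y, rng)
        pv = ml_engine.nested_cv_predict(X, y_perm, config,
                                         inner_seed=int(rng.integers(2**31 - 1)))
        rep = ml_engine.evaluate_predictions(y_perm, pv.predictions)
        for m in metrics:
            defined = getattr(rep, f"{m}_defined", True)
            null[m][it] = getattr(rep, m) if defined else np.nan
    return {
        m: PermutationResult(metric=m, observed=float(getattr(observed, m)),
                             null=null[m], seed=base_seed)
        for m in metrics
    }


def two_stage_screen(
    roi_datasets: Mapping[int, tuple[np.ndarray, np.ndarray]],
    config: ml_engine.CVConfig,
    stage1_iter: int = 100,
    stage2_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict[int, RoiScreenResult]:
    """Two-stage permutation screen across ROI-level lesion-presence models.

    ``roi_datasets`` maps ROI id -> (X, presence labels).  Stage 1 runs a
    ``stage1_iter``-permutation test on MCC; ROIs with p < ``alpha``
    advance to a ``stage2_iter``-permutation test on MCC, accuracy,
    precision and recall.  The final flag requires significance on all
    four.
    """
    base_seed = config.seed if seed is None else seed
    out: dict[int, RoiScreenResult] = {}
    for roi in sorted(roi_datasets):
        X, y_roi = roi_datasets[roi]
        roi_seed = (base_seed + 10_007 * int(roi)) % (2**31 - 1)
        stage1 = permutation_null(X, y_roi, config, metrics=("mcc",),
                                  n_iter=stage1_iter, seed=roi_seed)["mcc"]
        candidate = stage1.p < alpha
        stage2 = None
        if candidate:
            stage2 = permutation_null(X, y_roi, config, metrics=_METRICS,
                                      n_iter=stage2_iter, seed=roi_seed)
        out[roi] = RoiScreenResult(
            roi=int(roi),
            observed_mcc=stage1.observed,
            stage1_p=stage1.p,
            candidate=bool(candidate),
            stage2=stage2,
        )
    return out
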