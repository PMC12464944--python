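"""Linear-SVM training, MRMR feature selection and nested cross-validation.

The evaluation protocol is leave-one-out cross-validation (LOOCV) in the
outer loop — each subject is predicted by a model that never saw it — with
an inner cross-validation on the training portion to tune the SVM
regularization parameter C.  Class imbalance is handled by dynamic class
weights (n_total / (2 * n_class)) recomputed on each training set, and
optional MRMR feature selection is likewise fit inside each outer fold so
that no information about the held-out subject leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import stats_core

__all__ = [
    "CVConfig",
    "PredictionVector",
    "MrmrResult",
    "RepeatResult",
    "dynamic_class_weights",
    "train_linear_svm",
    "mrmr_select",
    "nested_cv_predict",
    "repeat_evaluate",
    "evaluate_predictions",
]

_DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings.

    inner            "kfold" (stratified, default k=5) or "loocv"
    C_grid           candidate SVM regularization values; ties during inner
                     selection break toward the smaller C
    weight_policy    "balanced" (dynamic class weights) or "none"
    mrmr_threshold   None disables feature selection; otherwise the MRMR
                     importance threshold tau (selection per outer fold)
    """

    inner: str = "kfold"
    inner_k: int = 5
    C_grid: tuple[float, ...] = _DEFAULT_C_GRID
    weight_policy: str = "balanced"
    mrmr_threshold: float | None = None
    mrmr_bins: int = 4
    mrmr_max_features: int | None = None
    n_repeats: int = 100
    seed: int = 0
    svm_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inner not in ("kfold", "loocv"):
            raise ValueError("inner must be 'kfold' or 'loocv'")
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be non-empty and positive")
        if self.weight_policy not in ("balanced", "none"):
            raise ValueError("weight_policy must be 'balanced' or 'none'")
        if self.mrmr_threshold is not None and self.mrmr_threshold < 0:
            raise ValueError("mrmr_threshold must be >= 0 when enabled")


@dataclass(frozen=True)
class PredictionVector:
    """Out-of-fold predictions from nested CV (one per subject)."""

    predictions: np.ndarray
    folds: np.ndarray
    chosen_C: np.ndarray
    n_selected: np.ndarray
    selected: tuple | None = None


@dataclass(frozen=True)
class MrmrResult:
    indices: np.ndarray  # selected features, rank order
    scores: np.ndarray  # MRMR importance per selected feature
    fallback: bool  # True if the threshold excluded everything


@dataclass(frozen=True)
class RepeatResult:
    """Per-repeat out-of-fold metrics and their mean/sd."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    mcc: np.ndarray

    def mean(self, metric: str) -> float:
        return float(np.nanmean(getattr(self, metric)))

    def sd(self, metric: str) -> float:
        return float(np.nanstd(getattr(self, metric), ddof=1)) if len(self.accuracy) > 1 else 0.0


def dynamic_class_weights(labels) -> dict:
    """Balanced weights n_total / (2 * n_class) per class.

    At the 48-patient / 107-control design this gives 1.6146 for patients
    and 0.7243 for controls; weight * count is equal across classes.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    n = labels.size
    return {c: n / (2.0 * k) for c, k in zip(classes.tolist(), counts.tolist())}


def train_linear_svm(X, y, C: float = 1.0, weights: dict | None = None,
                     seed: int = 0, tol: float = 1e-6) -> LinearSVC:
    """L2-regularized linear SVM (dual solver), deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each of two classes")
    model = LinearSVC(C=C, class_weight=weights, tol=tol, dual=True,
                      max_iter=100_000, random_state=seed)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# MRMR (mutual-information quotient) on equal-frequency binned features
# ---------------------------------------------------------------------------

def _bin_codes(X: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-frequency bin codes per column (computed on X itself)."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.quantile(X, qs, axis=0)  # (n_bins-1, f)
    codes = (X[None, :, :] > edges[:, None, :]).sum(axis=0)
    return codes.astype(np.int64), n_bins


def _mi_one_vs_many(ref: np.ndarray, ref_k: int, mat: np.ndarray, mat_k: int) -> np.ndarray:
    """Bias-corrected MI (nats) between one code vector and each matrix column.

    Plug-in MI overestimates by about (k_a - 1)(k_b - 1) / (2n) under
    independence (Miller-Madow); that bias is subtracted and the estimate
    clamped at 0, so uninformative features score near zero instead of
    inheriting the bias floor.
    """
    n, f = mat.shape
    combined = ref[:, None] * mat_k + mat + np.arange(f) * (ref_k * mat_k)
    counts = np.bincount(combined.ravel(), minlength=f * ref_k * mat_k)
    joint = counts.reshape(f, ref_k, mat_k) / n
    p_ref = joint.sum(axis=2, keepdims=True)
    p_mat = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * (np.log(joint) - np.log(p_ref) - np.log(p_mat))
    mi = np.where(joint > 0, term, 0.0).sum(axis=(1, 2))
    bias = (ref_k - 1) * (mat_k - 1) / (2.0 * n)
    return np.maximum(mi - bias, 0.0)


def mrmr_select(
    X,
    y,
    threshold: float,
    *,
    n_bins: int = 4,
    max_features: int | None = None,
) -> MrmrResult:
    """Greedy minimum-redundancy-maximum-relevance feature ranking.

    Features are binned to equal-frequency quartiles (by default) and
    scored by the mutual-information quotient: relevance MI(feature;
    label) divided by the mean MI with the already-selected features (the
    first feature's score is its raw relevance).  Ranking stops when the
    best score drops below ``threshold`` or ``max_features`` is reached
    (default min(n_samples - 1, 50), a guard against the upward bias of
    plug-in MI estimates at small n).  If the threshold excludes every
    feature the single most relevant feature is returned, flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    if f < 2:
        raise ValueError("need at least 2 features")
    if max_features is None:
        max_features = min(n - 1, 50)
    max_features = min(max_features, f)
    codes, kx = _bin_codes(X, n_bins)
    _, y_codes = np.unique(y, return_inverse=True)
    ky = y_codes.max() + 1
    relevance = _mi_one_vs_many(y_codes, ky, codes, kx)

    best = int(np.argmax(relevance))
    if relevance[best] < threshold:
        return MrmrResult(indices=np.array([best]),
                          scores=np.array([relevance[best]]), fallback=True)
    selected = [best]
    scores = [float(relevance[best])]
    red_sum = _mi_one_vs_many(codes[:, best], kx, codes, kx)
    while len(selected) < max_features:
        mean_red = red_sum / len(selected)
        # denominator floor (0.1 nat): after bias correction most
        # redundancies are ~0, and an unfloored quotient would promote
        # noise features purely for being unredundant
        cand = relevance / np.maximum(mean_red, 0.1)
        cand[selected] = -np.inf
        nxt = int(np.argmax(cand))
        if cand[nxt] < threshold:
            break
        selected.append(nxt)
        scores.append(float(cand[nxt]))
        red_sum = red_sum + _mi_one_vs_many(codes[:, nxt], kx, codes, kx)
    return MrmrResult(indices=np.array(selected), scores=np.array(scores), fallback=False)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

def _inner_select_C(X, y, config: CVConfig, rng_seed: int) -> float:
    """Pick C from the grid by inner-CV balanced accuracy (ties -> smaller C)."""
    if len(config.C_grid) == 1:
        return config.C_grid[0]
    if config.inner == "loocv":
        splits = [(np.delete(np.arange(len(y)), i), np.array([i]))
                  for i in range(len(y))]
    else:
        k = min(config.inner_k, int(np.bincount(y).min()))
        if k < 2:
            raise ValueError("inner stratified CV impossible: a class has < 2 members")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        splits = list(skf.split(X, y))
    preds = {C: np.empty(len(y), dtype=int) for C in config.C_grid}
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("inner fold lost a class; cannot stratify")
        w = dynamic_class_weights(y[tr]) if config.weight_policy == "balanced" else None
        for C in config.C_grid:
            model = train_linear_svm(X[tr], y[tr], C=C, weights=w,
                                     seed=config.seed, tol=config.svm_tol)
            preds[C][te] = model.predict(X[te])
    scores = {C: balanced_accuracy_score(y, preds[C]) for C in config.C_grid}
    best = max(sorted(config.C_grid), key=lambda C: (scores[C], -C))
    return best


def nested_cv_predict(X, y, config: CVConfig, *, inner_seed: int | None = None,
                      keep_selected: bool = False) -> PredictionVector:
    """Out-of-fold predictions: outer LOOCV, inner CV for C, per-fold MRMR.

    Every component that can adapt to the data — feature selection, class
    weights, the choice of C — is refit on the training portion of each
    outer fold, so each subject's prediction comes from a model that never
    saw that subject.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y disagree on the number of subjects")
    if len(np.unique(y)) != 2:
        raise ValueError("y must be binary")
    rng = np.random.default_rng(config.seed if inner_seed is None else inner_seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=n)
    predictions = np.empty(n, dtype=int)
    chosen_C = np.empty(n)
    n_selected = np.empty(n, dtype=int)
    selected_all: list[np.ndarray] = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        X_tr, y_tr = X[tr], y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("outer training fold lost a class")
        if config.mrmr_threshold is not None:
            sel = mrmr_select(X_tr, y_tr, config.mrmr_threshold,
                              n_bins=config.mrmr_bins,
                              max_features=config.mrmr_max_features)
            feat = sel.indices
        else:
            feat = np.arange(X.shape[1])
        C = _inner_select_C(X_tr[:, feat], y_tr, config, int(fold_seeds[i]))
        w = dynamic_class_weights(y_tr) if config.weight_policy == "balanced" else None
        model = train_linear_svm(X_tr[:, feat], y_tr, C=C, weights=w,
                                 seed=config.seed, tol=config.svm_tol)
        predictions[i] = model.predict(X[i:i + 1, feat])[0]
        chosen_C[i] = C
        n_selected[i] = len(feat)
        if keep_selected:
            selected_all.append(feat)
    return PredictionVector(
        predictions=predictions,
        folds=np.arange(n),
        chosen_C=chosen_C,
        n_selected=n_selected,
        selected=tuple(selected_all) if keep_selected else None,
    )


def evaluate_predictions(y_true, y_pred) -> stats_core.MetricsReport:
    """Accuracy / precision / recall / MCC of an out-of-fold prediction vector."""
    c = stats_core.confusion_counts(y_true, y_pred)
    return stats_core.confusion_metrics(c)


def repeat_evaluate(X, y, config: CVConfig, n_repeats: int | None = None) -> RepeatResult:
    """Repeat nested CV with reshuffled inner folds; aggregate the metrics.

    Only the inner-fold assignments change across repeats (the SVM solver
    seed stays fixed), so a configuration without inner randomness — a
    single C, or inner LOOCV — is exactly reproducible and has zero
    spread.
    """
    if n_repeats is None:
        n_repeats = config.n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(config.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    metrics = {m: np.empty(n_repeats) for m in ("accuracy", "precision", "recall", "mcc")}
    for rep in range(n_repeats):
        pv = nested_cv_predict(X, y, config, inner_seed=int(repeat_seeds[rep]))
        rep_metrics = evaluate_predictions(y, pv.predictions)
        for m in metrics:
            metrics[m][rep] = getattr(rep_metrics, m)
    return RepeatResult(**metrics)
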