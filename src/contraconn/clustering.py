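"""Silhouette-guided k-means clustering of patients on RRCz rows.

Patients with similar right-hemisphere connectivity patterns are grouped
by k-means (Euclidean distance, k-means++ initialization, 20 restarts);
the number of clusters is picked by the mean silhouette coefficient over
a candidate range (ties break toward the smaller k).  Cluster labels feed
the lesion-mapping contrasts (overlap maps, normalized difference maps,
voxelwise Barnard tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["ClusterResult", "silhouette_select_k", "cluster_patients"]


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: np.ndarray
    silhouette: dict[int, float]  # mean silhouette per candidate k (may be single)
    seed: int


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 20) -> KMeans:
    return KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                  random_state=seed).fit(X)


def silhouette_select_k(X, k_range=range(2, 11), seed: int = 0) -> tuple[int, dict[int, float]]:
    """Mean silhouette per candidate k; returns (k*, curve).

    k* maximizes the mean silhouette coefficient; ties break toward the
    smaller k.  Requires 2 <= k <= n_samples - 1 for every candidate.
    """
    X = np.asarray(X, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError(f"k_range must lie within [2, {len(X) - 1}]")
    curve: dict[int, float] = {}
    for k in ks:
        labels = _kmeans(X, k, seed).labels_
        curve[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best = max(ks, key=lambda k: (curve[k], -k))
    return best, curve


def cluster_patients(X, k: int, seed: int = 0) -> ClusterResult:
    """Final k-means partition (best inertia over 20 restarts)."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError("k cannot exceed the number of patients")
    km = _kmeans(X, k, seed)
    sil = float(silhouette_score(X, km.labels_)) if k < len(X) else float("nan")
    return ClusterResult(k=int(k), assignments=km.labels_.copy(),
                         silhouette={int(k): sil}, seed=int(seed))
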