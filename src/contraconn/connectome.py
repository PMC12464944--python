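"""Edge vectors, subject-level z-scoring (RRCz) and homotopic FC summaries.

Functional connectivity (FC) between two parcels is a Fisher-z-transformed
correlation.  A subject's right-hemisphere connectome is flattened to the
upper triangle of the N x N ROI-to-ROI matrix in row-major (i < j) order,
giving M = N(N-1)/2 edges (4950 at N = 100).  Subject-level z-scoring of
that edge vector (mean 0, sample sd 1) yields the RRCz representation used
by every classifier; it removes between-subject (and between-scanner)
offsets in overall connectivity strength so that models see only the
*pattern* of connectivity.
"""

from __future__ import annotations

import numpy as np

from .synthetic_cohort import Atlas

__all__ = [
    "fisher_z",
    "edge_vector",
    "edge_index",
    "edge_pairs",
    "rrcz_normalize",
    "homotopic_mean_fc",
    "nonhomotopic_mean_fc",
]


def fisher_z(r):
    """Fisher z-transform arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must satisfy |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def edge_index(i: int, j: int, n: int) -> int:
    """Position of edge (i, j), 0-based ROI indices i < j, in the row-major
    upper-triangle flattening of an n x n matrix."""
    if not 0 <= i < j < n:
        raise ValueError("need 0 <= i < j < n")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def edge_pairs(n: int) -> np.ndarray:
    """(M, 2) array of 0-based (i, j) ROI index pairs in edge order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def edge_vector(corr: np.ndarray, *, atol: float = 1e-8, transform: bool = True) -> np.ndarray:
    """Flatten a symmetric correlation matrix to its Fisher-z edge vector.

    The diagonal is ignored.  Set ``transform=False`` if the matrix already
    holds Fisher-z values.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr must be a square matrix")
    if not np.allclose(corr, corr.T, atol=atol):
        raise ValueError("corr must be symmetric")
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu]
    return fisher_z(vals) if transform else vals


def rrcz_normalize(edges: np.ndarray) -> np.ndarray:
    """Subject-level z-score: mean 0, sample sd 1 (ddof=1) per edge vector.

    Accepts a single edge vector or a (subjects x edges) matrix, normalized
    row-wise.  Invariant under affine rescaling of the input.
    """
    edges = np.asarray(edges, dtype=float)
    one_d = edges.ndim == 1
    mat = np.atleast_2d(edges)
    if not np.all(np.isfinite(mat)):
        raise ValueError("edge values must be finite")
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant edge vector cannot be z-scored")
    out = (mat - mat.mean(axis=1, keepdims=True)) / sd
    return out[0] if one_d else out


def _pair_block(interhemi_fc: np.ndarray, atlas: Atlas) -> np.ndarray:
    """Coerce cohort interhemispheric FC into (subjects, N, N) left x right."""
    fc = np.asarray(interhemi_fc, dtype=float)
    n = atlas.n_per_hemisphere
    if fc.ndim == 2:
        fc = fc[None]
    if fc.shape[1:] == (2 * n, 2 * n):
        fc = fc[:, :n, n:]
    if fc.shape[1:] != (n, n):
        raise ValueError(
            f"expected (subjects, {n}, {n}) left-right block or full "
            f"(subjects, {2 * n}, {2 * n}) matrices, got {fc.shape}"
        )
    return fc


def homotopic_mean_fc(interhemi_fc, atlas: Atlas, left_rois=None) -> np.ndarray:
    """Cohort-mean FC between each left ROI and its homotopic right partner.

    ``interhemi_fc`` is either full (subjects, 2N, 2N) matrices or the
    (subjects, N, N) left-by-right block, in Fisher-z units; rows follow
    left ROI order, columns right ROI order.  Returns one mean per
    requested left ROI (default: all, in atlas order).
    """
    fc = _pair_block(interhemi_fc, atlas)
    idx = atlas.left_roi_indices(left_rois)
    partner = np.array([atlas.homotopic_pair[atlas.left_ids[i]] - atlas.n_per_hemisphere - 1
                        for i in idx])
    return fc[:, idx, partner].mean(axis=0)


def nonhomotopic_mean_fc(interhemi_fc, atlas: Atlas, left_rois=None) -> np.ndarray:
    """Cohort-mean FC between each left ROI and the N-1 non-homotopic right ROIs."""
    fc = _pair_block(interhemi_fc, atlas)
    n = atlas.n_per_hemisphere
    idx = atlas.left_roi_indices(left_rois)
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        partner = atlas.homotopic_pair[atlas.left_ids[i]] - n - 1
        cols = np.arange(n) != partner
        out[k] = fc[:, i, cols].mean()
    return out
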