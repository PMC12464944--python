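"""Lesion-ROI intersection, overlap maps and voxelwise cluster contrasts.

All volumes are assumed co-registered on a shared voxel grid (no
resampling is performed here).  Intersection fractions are
|lesion ∩ ROI| / |ROI|; presence calls use an inclusive threshold
(default 1% of the ROI volume), and an ROI enters the regional analyses
when at least 20% of patients (count cutoff = ceil) have a lesion
present there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stats_core import barnard_exact
from .synthetic_cohort import Atlas, LesionMask

__all__ = [
    "IntersectionTable",
    "OverlapMap",
    "intersection_fraction",
    "intersection_table",
    "binarize_presence",
    "select_rois",
    "overlap_map",
    "normalized_difference_map",
    "voxelwise_barnard",
    "read_mask",
    "write_volume",
]


@dataclass(frozen=True)
class IntersectionTable:
    """Per-(patient, left ROI) lesion intersection fractions and presence calls."""

    fractions: np.ndarray  # (patients, left ROIs) in [0, 1]
    threshold: float
    left_ids: np.ndarray

    @property
    def presence(self) -> np.ndarray:
        return binarize_presence(self.fractions, self.threshold)


@dataclass(frozen=True)
class OverlapMap:
    """Voxelwise count of overlapping patient lesion masks."""

    counts: np.ndarray

    @property
    def max_overlap(self) -> int:
        return int(self.counts.max())

    @property
    def normalized(self) -> np.ndarray:
        if self.max_overlap == 0:
            raise ValueError("overlap map is empty; cannot normalize")
        return self.counts / self.max_overlap


def _check_grid(mask: LesionMask, atlas: Atlas) -> None:
    if mask.grid_shape != atlas.grid_shape:
        raise ValueError(
            f"mask grid {mask.grid_shape} does not match atlas grid {atlas.grid_shape}"
        )


def intersection_fraction(mask: LesionMask, atlas: Atlas, roi: int) -> float:
    """|lesion ∩ ROI| / |ROI| for one ROI."""
    _check_grid(mask, atlas)
    roi_mask = atlas.roi_mask(roi)
    vol = roi_mask.sum()
    if vol == 0:
        raise ValueError(f"ROI {roi} has no voxels")
    return float(np.logical_and(mask.voxels.astype(bool), roi_mask).sum() / vol)


def intersection_table(
    masks: list[LesionMask],
    atlas: Atlas,
    threshold: float = 0.01,
) -> IntersectionTable:
    """Intersection fractions of every patient lesion with every left ROI."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = atlas.n_per_hemisphere
    roi_volumes = np.bincount(atlas.label_image.ravel(), minlength=2 * n + 1)
    fractions = np.zeros((len(masks), n))
    for p, mask in enumerate(masks):
        _check_grid(mask, atlas)
        hit = np.bincount(atlas.label_image[mask.voxels.astype(bool)].ravel(),
                          minlength=2 * n + 1)
        fractions[p] = hit[1:n + 1] / roi_volumes[1:n + 1]
    return IntersectionTable(fractions=fractions, threshold=threshold,
                             left_ids=atlas.left_ids)


def binarize_presence(fractions: np.ndarray, t: float = 0.01) -> np.ndarray:
    """Presence = (fraction >= t); the boundary is lesion-present."""
    if not 0 < t <= 1:
        raise ValueError("threshold must be in (0, 1]")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in [0, 1]")
    return (fractions >= t).astype(int)


def select_rois(presence: np.ndarray, min_patient_fraction: float = 0.2,
                left_ids=None) -> np.ndarray:
    """ROIs whose presence count reaches ceil(min_patient_fraction * n_patients).

    At the emulated design (48 patients, 20%) the cutoff is n >= 10.
    Returns ROI ids (columns of ``presence`` mapped through ``left_ids``,
    default 1-based column order).
    """
    presence = np.asarray(presence)
    if presence.ndim != 2 or presence.shape[0] < 1:
        raise ValueError("presence must be (patients x ROIs) with >= 1 patient")
    cutoff = math.ceil(min_patient_fraction * presence.shape[0])
    counts = presence.sum(axis=0)
    ids = np.arange(1, presence.shape[1] + 1) if left_ids is None else np.asarray(left_ids)
    return ids[counts >= cutoff]


def overlap_map(masks: list[LesionMask]) -> OverlapMap:
    """Voxelwise sum of binary lesion masks."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].grid_shape
    counts = np.zeros(shape, dtype=int)
    for m in masks:
        if m.grid_shape != shape:
            raise ValueError("all masks must share one grid")
        counts += m.voxels.astype(int)
    return OverlapMap(counts=counts)


def normalized_difference_map(map_a: OverlapMap, map_b: OverlapMap) -> np.ndarray:
    """A/max_A - B/max_B per voxel, in [-1, 1]; positive favors the first map."""
    if map_a.counts.shape != map_b.counts.shape:
        raise ValueError("overlap maps must share one grid")
    return map_a.normalized - map_b.normalized


def _barnard_p_map(stack: np.ndarray, in_a: np.ndarray, min_total_overlap: int,
                   grid_step: float,
                   cache: dict[tuple[int, int], float]) -> np.ndarray:
    n1, n2 = int(in_a.sum()), int((~in_a).sum())
    count_a = stack[in_a].sum(axis=0)
    count_b = stack[~in_a].sum(axis=0)
    total = count_a + count_b
    p_map = np.ones(stack.shape[1:])
    for idx in np.argwhere(total >= min_total_overlap):
        key = (int(count_a[tuple(idx)]), int(count_b[tuple(idx)]))
        if key not in cache:
            a, b = key
            cache[key] = barnard_exact([[a, b], [n1 - a, n2 - b]], grid_step=grid_step)
        p_map[tuple(idx)] = cache[key]
    return p_map


def voxelwise_barnard(
    masks: list[LesionMask],
    cluster_labels,
    alpha: float = 0.05,
    min_total_overlap: int = 1,
    grid_step: float = 1e-3,
    max_t_permutations: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise Barnard exact tests of lesion overlap between two clusters.

    At each voxel lesioned by at least ``min_total_overlap`` patients, a
    2x2 table (lesion present/absent x cluster) is tested; other voxels
    get p = 1.  Returns ``(p_map, significance_mask)`` with the mask
    thresholded at ``alpha`` — uncorrected by default, mirroring an
    exploratory cluster-contrast map.

    ``max_t_permutations > 0`` switches the significance mask to a
    family-wise-corrected one: cluster labels are permuted, the minimum
    p over voxels recorded per permutation, and a voxel is significant
    when its p is below the alpha-quantile of that min-p null (maxT /
    minP correction).
    """
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two clusters required, got {len(uniq)}")
    if len(labels) != len(masks):
        raise ValueError("one cluster label per mask required")
    in_a = labels == uniq[0]
    stack = np.stack([m.voxels.astype(bool) for m in masks])
    cache: dict[tuple[int, int], float] = {}
    p_map = _barnard_p_map(stack, in_a, min_total_overlap, grid_step, cache)
    if max_t_permutations <= 0:
        return p_map, p_map < alpha
    rng = np.random.default_rng(seed)
    min_ps = np.empty(max_t_permutations)
    for it in range(max_t_permutations):
        perm = rng.permutation(len(labels))
        null_map = _barnard_p_map(stack, in_a[perm], min_total_overlap,
                                  grid_step, cache)
        min_ps[it] = null_map.min()
    threshold = np.quantile(min_ps, alpha)
    return p_map, p_map <= threshold


def read_mask(path) -> tuple[LesionMask, np.ndarray]:
    """Load a binary NIfTI lesion mask; returns (mask, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LesionMask(voxels=(data > 0).astype(np.int8)), img.affine


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a volume (mask, overlap/difference/p map) as NIfTI, keeping the affine."""
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
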