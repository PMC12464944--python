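"""Lesion-ROI intersections, overlap maps and voxelwise cluster tests."""

import numpy as np
import pytest
from scipy import ndimage

from contraconn import lesion_mapping as lm
from contraconn import stats_core as sc
from contraconn import synthetic_cohort as syn


def _mask_like(atlas, voxels):
    return syn.LesionMask(voxels=voxels.astype(np.int8))


class TestIntersectionFraction:
    def test_superset_gives_one(self, toy_atlas):
        mask = _mask_like(toy_atlas, np.ones(toy_atlas.grid_shape))
        assert lm.intersection_fraction(mask, toy_atlas, 4) == 1.0

    def test_disjoint_gives_zero(self, toy_atlas):
        right_roi = toy_atlas.n_per_hemisphere + 2
        mask = _mask_like(toy_atlas, toy_atlas.roi_mask(right_roi))
        assert lm.intersection_fraction(mask, toy_atlas, 1) == 0.0

    def test_partial_fraction_and_presence_boundary(self, toy_atlas):
        roi = 2
        roi_voxels = np.argwhere(toy_atlas.roi_mask(roi))
        vol = len(roi_voxels)
        take = max(1, round(0.01 * vol))
        voxels = np.zeros(toy_atlas.grid_shape)
        for v in roi_voxels[:take]:
            voxels[tuple(v)] = 1
        mask = _mask_like(toy_atlas, voxels)
        frac = lm.intersection_fraction(mask, toy_atlas, roi)
        assert frac == pytest.approx(take / vol)

    def test_grid_mismatch_rejected(self, toy_atlas):
        mask = _mask_like(toy_atlas, np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            lm.intersection_fraction(mask, toy_atlas, 1)

    def test_monotone_under_dilation(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 3, radius=2, seed=0)
        dilated = _mask_like(toy_atlas, ndimage.binary_dilation(mask.voxels))
        for roi in toy_atlas.left_ids:
            assert (lm.intersection_fraction(dilated, toy_atlas, int(roi))
                    >= lm.intersection_fraction(mask, toy_atlas, int(roi)))


class TestBinarizePresence:
    def test_boundary_inclusive(self):
        fr = np.array([[0.009999, 0.01, 0.5]])
        assert lm.binarize_presence(fr, 0.01).tolist() == [[0, 1, 1]]

    def test_full_coverage_threshold(self):
        fr = np.array([[0.999, 1.0]])
        assert lm.binarize_presence(fr, 1.0).tolist() == [[0, 1]]

    def test_presence_counts_monotone_in_threshold(self, rng):
        fr = rng.uniform(size=(10, 6))
        counts = [lm.binarize_presence(fr, t).sum() for t in (0.1, 0.3, 0.5, 0.9)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            lm.binarize_presence(np.array([[0.5]]), 0.0)


class TestSelectRois:
    def test_study_design_cutoff(self):
        presence = np.zeros((48, 5), dtype=int)
        presence[:10, 0] = 1  # exactly at cutoff
        presence[:9, 1] = 1  # one short
        ids = lm.select_rois(presence, 0.2)
        assert ids.tolist() == [1]

    def test_small_cohort_ceil(self):
        presence = np.zeros((5, 3), dtype=int)
        presence[0, 2] = 1  # ceil(0.2*5)=1
        assert lm.select_rois(presence, 0.2).tolist() == [3]

    def test_all_zero_empty(self):
        assert lm.select_rois(np.zeros((8, 4), dtype=int), 0.2).size == 0


class TestOverlapMaps:
    def test_single_mask_identity(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 2, radius=3, seed=1)
        om = lm.overlap_map([mask])
        assert np.array_equal(om.counts, mask.voxels)

    def test_k_identical_masks(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 2, radius=3, seed=1)
        om = lm.overlap_map([mask] * 4)
        assert om.max_overlap == 4
        assert np.array_equal(om.counts, 4 * mask.voxels)

    def test_disjoint_masks_max_one(self, toy_atlas):
        a = np.zeros(toy_atlas.grid_shape)
        b = np.zeros(toy_atlas.grid_shape)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        om = lm.overlap_map([_mask_like(toy_atlas, a), _mask_like(toy_atlas, b)])
        assert om.max_overlap == 1


class TestNormalizedDifferenceMap:
    def test_equal_maps_zero(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 3, radius=2, seed=0)
        om = lm.overlap_map([mask])
        assert np.all(lm.normalized_difference_map(om, om) == 0)

    def test_scale_invariance(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 3, radius=2, seed=0)
        a = lm.overlap_map([mask] * 2)
        b = lm.overlap_map([mask])
        assert np.allclose(lm.normalized_difference_map(a, b), 0)

    def test_bounds_and_antisymmetry(self, toy_atlas):
        m1 = syn.generate_lesion_mask(toy_atlas, 2, radius=2, seed=1)
        m2 = syn.generate_lesion_mask(toy_atlas, 7, radius=3, seed=2)
        a, b = lm.overlap_map([m1]), lm.overlap_map([m2])
        d = lm.normalized_difference_map(a, b)
        assert d.min() >= -1 and d.max() <= 1
        assert np.allclose(d, -lm.normalized_difference_map(b, a))

    def test_bound_attained(self, toy_atlas):
        a = np.zeros(toy_atlas.grid_shape)
        a[1, 1, 1] = 1
        b = np.zeros(toy_atlas.grid_shape)
        b[3, 3, 3] = 1
        d = lm.normalized_difference_map(
            lm.overlap_map([_mask_like(toy_atlas, a)]),
            lm.overlap_map([_mask_like(toy_atlas, b)]),
        )
        assert d[1, 1, 1] == 1.0 and d[3, 3, 3] == -1.0


class TestVoxelwiseBarnard:
    def test_uniform_lesion_gives_p_one(self):
        shape = (4, 4, 1)
        masks = [_mask_like(None, np.ones(shape)) for _ in range(8)]
        labels = [0] * 3 + [1] * 5
        p_map, sig = lm.voxelwise_barnard(masks, labels)
        assert np.all(p_map == 1.0) and not sig.any()

    def test_extreme_voxel_matches_exact_test(self):
        """A voxel lesioned by all 9 cluster-A and no cluster-B patients
        must reproduce the unconditional exact p for table (9,0;0,39)."""
        shape = (2, 2, 1)
        masks = []
        for i in range(48):
            v = np.zeros(shape)
            if i < 9:
                v[0, 0, 0] = 1
            masks.append(_mask_like(None, v))
        labels = [0] * 9 + [1] * 39
        p_map, _ = lm.voxelwise_barnard(masks, labels)
        expected = sc.barnard_exact([[9, 0], [0, 39]])
        assert p_map[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert p_map[1, 1, 0] == 1.0  # below the overlap floor

    def test_cluster_label_swap_invariant(self, rng):
        shape = (3, 3, 2)
        masks = [_mask_like(None, (rng.uniform(size=shape) < 0.4)) for _ in range(14)]
        labels = np.array([0] * 6 + [1] * 8)
        p1, _ = lm.voxelwise_barnard(masks, labels)
        p2, _ = lm.voxelwise_barnard(masks, 1 - labels)
        assert np.allclose(p1, p2)

    def test_type_one_error_rate_near_alpha(self, rng):
        """Identical lesion distributions in both clusters: the fraction of
        p < 0.05 voxels stays at or below ~alpha (Barnard is conservative
        at small counts)."""
        shape = (8, 8, 8)
        masks = [_mask_like(None, (rng.uniform(size=shape) < 0.35)) for _ in range(24)]
        labels = np.array([0] * 10 + [1] * 14)
        p_map, sig = lm.voxelwise_barnard(masks, labels)
        frac = sig.mean()
        se = np.sqrt(0.05 * 0.95 / sig.size)
        assert frac <= 0.05 + 3 * se

    def test_p_values_in_unit_interval(self, rng):
        shape = (3, 3, 1)
        masks = [_mask_like(None, (rng.uniform(size=shape) < 0.5)) for _ in range(10)]
        p_map, _ = lm.voxelwise_barnard(masks, [0] * 4 + [1] * 6)
        assert np.all((p_map > 0) & (p_map <= 1))

    def test_more_than_two_clusters_rejected(self, toy_atlas):
        mask = syn.generate_lesion_mask(toy_atlas, 2, radius=2, seed=0)
        with pytest.raises(ValueError):
            lm.voxelwise_barnard([mask] * 3, [0, 1, 2])


class TestMaxTCorrection:
    def test_correction_is_more_conservative(self, rng):
        shape = (5, 5, 2)
        masks = [_mask_like(None, (rng.uniform(size=shape) < 0.4)) for _ in range(16)]
        labels = [0] * 7 + [1] * 9
        _, sig_unc = lm.voxelwise_barnard(masks, labels)
        _, sig_cor = lm.voxelwise_barnard(masks, labels, max_t_permutations=30)
        assert sig_cor.sum() <= sig_unc.sum()
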