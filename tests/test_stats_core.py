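"""Closed-form statistics: metrics, empirical p, rank tests, Barnard."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from contraconn import stats_core as sc


class TestConfusionMetrics:
    def test_worked_example(self):
        # 48-subject ROI-level model: 9 TP, 4 FP, 5 FN, 30 TN
        rep = sc.confusion_metrics(sc.ConfusionCounts(9, 4, 5, 30))
        assert rep.accuracy == pytest.approx(0.8125)
        assert rep.precision == pytest.approx(9 / 13)
        assert rep.recall == pytest.approx(9 / 14)
        assert round(rep.accuracy, 2) == 0.81
        assert round(rep.precision, 2) == 0.69
        assert round(rep.recall, 2) == 0.64

    def test_perfect_classifier(self):
        rep = sc.confusion_metrics(sc.ConfusionCounts(5, 0, 0, 9))
        assert (rep.accuracy, rep.precision, rep.recall, rep.mcc) == (1, 1, 1, 1)

    def test_all_negative_predictor_flags_precision(self):
        rep = sc.confusion_metrics(sc.ConfusionCounts(0, 0, 4, 8))
        assert math.isnan(rep.precision) and not rep.precision_defined
        assert rep.recall == 0 and rep.recall_defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.ConfusionCounts(-1, 0, 0, 5)


class TestMcc:
    def test_worked_example_rounds_to_054(self):
        value = sc.mcc(sc.ConfusionCounts(9, 4, 5, 30))
        assert value == pytest.approx(0.5372, abs=5e-5)
        assert round(value, 2) == 0.54

    def test_unique_matrix_for_reported_roi_metrics(self):
        """Enumeration: (9,4,5,30) is the only 48-subject matrix with >= 10
        positives whose accuracy/precision/recall round to 0.81/0.69/0.64."""
        matches = []
        for tp, fp, fn in itertools.product(range(49), repeat=3):
            tn = 48 - tp - fp - fn
            if tn < 0 or tp + fn < 10:
                continue
            if tp + fp == 0 or tp + fn == 0:
                continue
            acc = (tp + tn) / 48
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            if (round(acc, 2), round(prec, 2), round(rec, 2)) == (0.81, 0.69, 0.64):
                matches.append((tp, fp, fn, tn))
        assert matches == [(9, 4, 5, 30)]
        assert round(sc.mcc(sc.ConfusionCounts(*matches[0])), 2) == 0.54

    def test_label_swap_invariance(self):
        a = sc.mcc(sc.ConfusionCounts(9, 4, 5, 30))
        b = sc.mcc(sc.ConfusionCounts(30, 5, 4, 9))  # positive<->negative swap
        assert a == pytest.approx(b)

    def test_degenerate_returns_zero_flagged(self):
        rep = sc.confusion_metrics(sc.ConfusionCounts(0, 0, 3, 7))
        assert rep.mcc == 0.0 and not rep.mcc_defined


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0, 1000, 0.001), (27, 1000, 0.028), (1000, 1000, 1.0)],
    )
    def test_values(self, r, n, expected):
        assert round(sc.empirical_p(r, n), 3) == expected

    def test_monotone_in_r_and_floor(self):
        ps = [sc.empirical_p(r, 50) for r in range(51)]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert ps[0] == pytest.approx(1 / 51)
        assert ps[-1] == 1.0

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            sc.empirical_p(11, 10)


def _exact_ranksum_p(x, y):
    """Exhaustive two-sided rank-sum p over all label assignments (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2
    stats = [
        abs(ranks[list(c)].sum() - mean)
        for c in itertools.combinations(range(len(pooled)), nx)
    ]
    return np.mean([s >= abs(obs - mean) - 1e-12 for s in stats])


class TestWilcoxonRanksum:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        z, p = sc.wilcoxon_ranksum(x, x)
        assert abs(z) < 0.2 and p >= 0.99

    def test_small_sample_vs_exact_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        _, p = sc.wilcoxon_ranksum(x, y)
        exact = _exact_ranksum_p(np.array(x), np.array(y))
        # the normal approximation with continuity correction should land
        # within ~0.1 of the exact tail probability at n=2,2
        assert p == pytest.approx(exact, abs=0.12)

    def test_tie_correction_reduces_variance(self):
        x = [1.0, 1.0, 2.0, 2.0, 5.0]
        y = [1.0, 2.0, 2.0, 3.0, 3.0]
        z_tc, _ = sc.wilcoxon_ranksum(x, y, tie_correction=True)
        z_raw, _ = sc.wilcoxon_ranksum(x, y, tie_correction=False)
        assert abs(z_tc) >= abs(z_raw)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_ranksum([], [1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 30), min_size=3, max_size=8),
        y=st.lists(st.integers(0, 30), min_size=3, max_size=8),
    )
    def test_antisymmetric_and_bounded(self, x, y):
        z_xy, p_xy = sc.wilcoxon_ranksum(x, y)
        z_yx, p_yx = sc.wilcoxon_ranksum(y, x)
        assert z_xy == pytest.approx(-z_yx, abs=1e-12)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        assert 0 <= p_xy <= 1


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = sc.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (2,1,1): 1 - 6*6/24 = -0.5
        rho, _ = sc.spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_reversal_negates(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5]
        r1, _ = sc.spearman(x, y)
        r2, _ = sc.spearman(x, [-v for v in y])
        assert r1 == pytest.approx(-r2)

    def test_constant_input_flagged(self):
        rho, p = sc.spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)


def _barnard_enumeration_oracle(a, b, c, d, grid_step=1e-4):
    """Independent brute-force: tail prob over all outcome tables, maximized
    on a dense nuisance grid, with the pooled-score tail criterion."""
    n1, n2 = a + c, b + d

    def score(x1, x2):
        p1, p2 = x1 / n1, x2 / n2
        pp = (x1 + x2) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
        return 0.0 if var <= 0 else (p1 - p2) / math.sqrt(var)

    t_obs = abs(score(a, b))
    best = 0.0
    for pi in np.arange(grid_step, 1.0, grid_step):
        total = 0.0
        for x1 in range(n1 + 1):
            px1 = math.comb(n1, x1) * pi**x1 * (1 - pi) ** (n1 - x1)
            for x2 in range(n2 + 1):
                if abs(score(x1, x2)) >= t_obs - 1e-10:
                    total += px1 * math.comb(n2, x2) * pi**x2 * (1 - pi) ** (n2 - x2)
        best = max(best, total)
    return best


class TestBarnardExact:
    def test_equal_proportions_give_one(self):
        assert sc.barnard_exact([[3, 3], [7, 7]]) == 1.0

    def test_extreme_table_matches_enumeration_oracle(self):
        # all 9 cluster-A patients lesioned, none of 39 cluster-B patients
        ours = sc.barnard_exact([[9, 0], [0, 39]], grid_step=1e-4)
        oracle = _barnard_enumeration_oracle(9, 0, 0, 39, grid_step=1e-3)
        assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("table", [[[3, 1], [2, 4]], [[5, 2], [1, 6]]])
    def test_agrees_with_independent_implementation(self, table):
        ours = sc.barnard_exact(table, grid_step=1e-4)
        ref = sps.barnard_exact(table, alternative="two-sided", pooled=True)
        assert ours == pytest.approx(ref.pvalue, abs=1e-4)

    def test_symmetry_under_row_and_column_swap(self):
        t = [[6, 2], [3, 7]]
        swapped = [[7, 3], [2, 6]]
        assert sc.barnard_exact(t) == pytest.approx(sc.barnard_exact(swapped))

    def test_maximization_dominates_pointwise(self):
        # p >= the single-pi tail probability for any pi
        a, b, c, d = 5, 1, 2, 6
        p = sc.barnard_exact([[a, b], [c, d]], grid_step=1e-3)
        n1, n2 = a + c, b + d
        for pi in (0.2, 0.5, 0.8):
            x1 = np.arange(n1 + 1)[:, None]
            x2 = np.arange(n2 + 1)[None, :]
            t_all = np.abs(sc._wald_score(x1, x2, n1, n2))
            t_obs = abs(sc._wald_score(np.array([a]), np.array([b]), n1, n2)[0])
            prob = (
                sps.binom.pmf(np.arange(n1 + 1), n1, pi)[:, None]
                * sps.binom.pmf(np.arange(n2 + 1), n2, pi)[None, :]
            )
            assert p >= prob[t_all >= t_obs - 1e-10].sum() - 1e-9

    def test_bad_input(self):
        with pytest.raises(ValueError):
            sc.barnard_exact([[1, 0], [2, 0]])  # empty second group
        with pytest.raises(ValueError):
            sc.barnard_exact([[1, -1], [2, 3]])
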