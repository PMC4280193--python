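import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from commlesion import (
    correlate_change_distance,
    distance_correlation_table,
    distance_from_lesion,
    fdr_adjust,
    make_change_report,
    paired_ttest_per_node,
    permutation_test_curves,
    report_change_locations,
    sensitivity_summary,
)

from conftest import make_connectome


def exact_permutation_p(sums_a, sums_b):
    """Oracle: enumerate every group relabelling of the pooled curves."""
    pooled = list(sums_a) + list(sums_b)
    ka = len(sums_a)
    idx = range(len(pooled))
    t_obs = np.mean(sums_a) - np.mean(sums_b)
    count = total = 0
    for combo in itertools.combinations(idx, ka):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in idx if i not in combo]
        t = np.mean(a) - np.mean(b)
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return count / total


def brute_bh(p):
    """Oracle: sort, scale by n/rank, cumulative min from the right."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestPermutationTest:
    def test_identical_constant_sets_give_p_one(self):
        curves = np.ones((4, 6))
        t, p = permutation_test_curves(curves, curves.copy(), n_perm=500,
                                       rng=np.random.default_rng(0))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_reach_minimal_p(self):
        a = np.ones((4, 5))
        b = np.zeros((4, 5))
        # oracle: only the 2 extreme assignments of C(8,4)=70 match |T_obs|
        exact = exact_permutation_p(a.sum(axis=1), b.sum(axis=1))
        assert exact == pytest.approx(2 / 70)
        _, p = permutation_test_curves(a, b, n_perm=20000,
                                       rng=np.random.default_rng(1))
        assert p == pytest.approx(exact, abs=0.01)

    def test_matches_exact_enumeration_on_noisy_curves(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.5, 0.3, size=(4, 6))
        b = rng.normal(0.2, 0.3, size=(4, 6))
        exact = exact_permutation_p(a.sum(axis=1), b.sum(axis=1))
        _, p = permutation_test_curves(a, b, n_perm=20000,
                                       rng=np.random.default_rng(2))
        assert p == pytest.approx(exact, abs=0.02)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            permutation_test_curves(np.ones((2, 3)), np.ones((2, 4)))

    def test_super_uniform_under_null(self):
        """Type-I error of the permutation p stays at or below nominal."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            pooled = rng.normal(size=(8, 4))
            _, p = permutation_test_curves(pooled[:4], pooled[4:],
                                           n_perm=200, rng=rng)
            rejections += p <= 0.05
        # binomial(400, 0.05) three-sigma upper bound
        assert rejections / n_sim <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)


class TestPairedTTest:
    def test_no_change_gives_p_one(self):
        x = np.arange(12.0).reshape(3, 4)
        t, p, zero = paired_ttest_per_node(x, x.copy())
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)
        assert not zero.any()

    def test_hand_computed_t_and_p(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 * sqrt(3), df = 2
        base = np.array([[1.0], [2.0], [3.0]])
        les = np.zeros((3, 1))
        t, p, _ = paired_ttest_per_node(base, les)
        assert t[0] == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert p[0] == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), 2), abs=1e-12)
        assert p[0] == pytest.approx(0.0742, abs=5e-4)

    def test_consistent_direction_gives_small_p(self):
        rng = np.random.default_rng(0)
        base = np.ones((6, 3)) + rng.normal(0, 1e-3, (6, 3))
        les = np.zeros((6, 3))
        _, p, _ = paired_ttest_per_node(base, les)
        assert np.all(p < 1e-6)

    def test_zero_variance_nonzero_effect_flagged(self):
        base = np.full((4, 2), 5.0)
        les = np.full((4, 2), 3.0)
        t, p, zero = paired_ttest_per_node(base, les)
        assert np.all(np.isinf(t)) and np.all(p == 0.0) and zero.all()

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(9, 5))
        les = rng.normal(size=(9, 5))
        t, p, _ = paired_ttest_per_node(base, les)
        ref = sps.ttest_rel(base, les, axis=0)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="2 subjects"):
            paired_ttest_per_node(np.ones((1, 3)), np.zeros((1, 3)))


class TestFDR:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.01, 0.02, 0.5])), [0.03, 0.03, 0.5]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(fdr_adjust(np.ones(5)), 1.0)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.2])), [0.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(2, 21))
        np.testing.assert_allclose(fdr_adjust(p), brute_bh(p), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="0, 1"):
            fdr_adjust(np.array([0.5, 1.2]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        assert np.all(fdr_adjust(p) >= p - 1e-15)


class TestSensitivitySummary:
    def test_counts_and_earliest(self):
        reports = [_fake_report(1, np.ones(4)),
                   _fake_report(2, np.ones(4)),
                   _fake_report(3, np.array([1, 1, 1, 0.01]))]
        counts, earliest = sensitivity_summary(reports)
        np.testing.assert_array_equal(counts, [0, 0, 1])
        assert earliest == 3

    def test_no_significance_gives_inf(self):
        counts, earliest = sensitivity_summary([_fake_report(1, np.ones(3))])
        assert math.isinf(earliest)

    def test_lesioned_nodes_can_be_excluded(self):
        rep = _fake_report(1, np.array([0.01, 0.01, 1.0]))
        counts, earliest = sensitivity_summary(
            [rep], lesioned_nodes=[0], include_lesioned=False
        )
        np.testing.assert_array_equal(counts, [1])
        assert earliest == 1


def _fake_report(step, p_adj):
    from commlesion.stats import ChangeReport

    n = len(p_adj)
    return ChangeReport(
        metric="Sw", step=step, mean_change=np.zeros(n), t=np.zeros(n),
        p_raw=np.asarray(p_adj, float), p_adj=np.asarray(p_adj, float),
    )


class TestDistanceFromLesion:
    def test_path3_binary(self, path3):
        np.testing.assert_array_equal(
            distance_from_lesion(path3, [0], "binary"), [0, 1, 2]
        )

    def test_two_sites_take_min(self, path3):
        d01 = distance_from_lesion(path3, [0], "binary")
        d21 = distance_from_lesion(path3, [2], "binary")
        both = distance_from_lesion(path3, [0, 2], "binary")
        np.testing.assert_array_equal(both, np.minimum(d01, d21))

    def test_euclidean_3_4_5(self):
        coords = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        c = make_connectome([[0, 1], [1, 0]], coords=coords)
        d = distance_from_lesion(c, [0], "euclidean")
        assert d[1] == pytest.approx(5.0)

    def test_euclidean_without_coords_raises(self, path3):
        with pytest.raises(ValueError, match="coordinates"):
            distance_from_lesion(path3, [0], "euclidean")


class TestCorrelations:
    def test_linear_decreasing_pearson(self):
        d = np.arange(10.0)
        assert correlate_change_distance(5 - 2 * d, d, "pearson") == pytest.approx(-1.0)

    def test_monotone_nonlinear_spearman(self):
        d = np.arange(1.0, 11.0)
        ch = 1.0 / d**3
        assert correlate_change_distance(ch, d, "spearman") == pytest.approx(-1.0)
        assert abs(correlate_change_distance(ch, d, "pearson")) < 1.0

    def test_constant_input_returns_sentinel(self):
        assert correlate_change_distance(np.ones(5), np.arange(5.0)) is None

    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = rng.permutation(x)
        assert abs(correlate_change_distance(x, y, "pearson")) < 0.15

    def test_table_layout_and_conventions(self):
        rng = np.random.default_rng(1)
        changes = {"Sw": rng.normal(size=(4, 10)), "CBC": rng.normal(size=(4, 10))}
        dist = {"DistB": np.arange(10.0), "DistW": rng.random(10)}
        tbl = distance_correlation_table(changes, dist, exclude=[0])
        assert set(tbl["metric"]) == {"Sw", "CBC"}
        assert set(tbl["distance"]) == {"DistB", "DistW"}
        assert tbl["average"].abs().max() <= 1.0
        assert tbl["individual_mean"].abs().max() <= 1.0


class TestChangeLocations:
    def test_fraction_counting(self):
        reports = [_fake_report(1, np.array([0.01, 1, 1]))] * 9 + [
            _fake_report(1, np.ones(3))
        ] * 16
        tbl = report_change_locations(reports, k=3)
        assert tbl.iloc[0]["fraction"] == pytest.approx(9 / 25)

    def test_damaged_nodes_excluded(self):
        reports = [_fake_report(1, np.array([0.01, 0.02, 1.0]))]
        tbl = report_change_locations(reports, damaged_nodes=[0], k=3)
        assert 1 not in set(tbl["node"])  # node index 0 is 1-based "1"
        assert set(tbl["node"]) == {2}

    def test_empty_when_nothing_significant(self):
        tbl = report_change_locations([_fake_report(1, np.ones(4))])
        assert tbl.empty


class TestChangeReport:
    def test_adjusted_ge_raw_and_significance_set(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 6))
        les = base - np.array([2.0, 0, 0, 0, 0, 0])  # strong effect at node 0
        rep = make_change_report("Sw", 1, base, les)
        assert np.all(rep.p_adj >= rep.p_raw - 1e-15)
        assert 0 in rep.significant
        # mean_change is baseline - lesioned: a drop shows as +2
        assert rep.mean_change[0] == pytest.approx(2.0, abs=1e-9)
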