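import itertools
import math

import networkx as nx
import numpy as np
import pytest

from commlesion import (
    betweenness,
    characteristic_path_length,
    communicability_assortativity,
    communicability_binary,
    communicability_centrality,
    communicability_weighted,
    degree_strength,
    distance_matrix,
    global_efficiency,
    identify_hubs,
    node_communicability,
    node_metric_table,
    top_node_density,
)
from commlesion.metrics import NodeMetricVector, PairMatrix

from conftest import make_connectome, random_connectome


def series_expm(M, kmax=30):
    """Independent oracle: truncated walk series sum_k M^k / k!."""
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, kmax + 1):
        term = term @ M / k
        out = out + term
    return out


def brute_betweenness(c, weighted=False):
    """Oracle: enumerate all simple paths, keep the shortest, credit interior
    nodes fractionally.  Only feasible for tiny graphs."""
    n = c.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(c.W, 1))
    for i, j in zip(ii, jj):
        G.add_edge(int(i), int(j))
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not nx.has_path(G, s, t):
            continue
        paths = list(nx.all_simple_paths(G, s, t))

        def plen(p):
            if not weighted:
                return len(p) - 1
            return sum(1.0 / c.W[a, b] for a, b in zip(p, p[1:]))

        lengths = [plen(p) for p in paths]
        best = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if l <= best * (1 + 1e-12)]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


class TestCommunicabilityClosedForms:
    def test_single_edge_is_sinh_one(self, single_edge):
        cm = communicability_binary(single_edge).values
        assert cm[0, 1] == pytest.approx(math.sinh(1.0), abs=1e-9)
        assert cm[0, 0] == pytest.approx(math.cosh(1.0), abs=1e-9)

    def test_empty_graph_is_identity(self, empty3):
        cm = communicability_binary(empty3).values
        np.testing.assert_allclose(cm, np.eye(3), atol=1e-12)

    def test_k3_spectral_value(self, k3):
        # eigenvalues of K3 adjacency: {2, -1, -1}
        expected = (math.e**2 - math.exp(-1)) / 3.0
        cm = communicability_binary(k3).values
        assert cm[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_k3_normalized_weighted_value(self, k3):
        # normalized matrix is A/2, eigenvalues {1, -1/2, -1/2}
        expected = (math.e - math.exp(-0.5)) / 3.0
        for w in (1.0, 0.01, 250.0):
            c = k3.with_weights(k3.W * w)
            cm = communicability_weighted(c, normalize=True).values
            assert cm[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_two_nodes_unnormalized_is_sinh_w(self):
        c = make_connectome([[0, 1.7], [1.7, 0]])
        cm = communicability_weighted(c, normalize=False).values
        assert cm[0, 1] == pytest.approx(math.sinh(1.7), abs=1e-9)

    def test_isolated_node_has_unit_diagonal(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        cm = communicability_weighted(make_connectome(W), normalize=True).values
        assert cm[2, 2] == pytest.approx(1.0)
        assert cm[2, 0] == 0.0 and cm[2, 1] == 0.0


class TestCommunicabilityProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_truncated_series(self, seed):
        n = 4 + seed % 5
        c = random_connectome(n, 0.5, seed=seed, weighted=(seed % 2 == 0))
        cm = communicability_binary(c).values
        np.testing.assert_allclose(
            cm, series_expm(c.binary_adjacency()), atol=1e-9
        )
        cmw = communicability_weighted(c, normalize=True).values
        from commlesion.metrics import _normalized_matrix

        np.testing.assert_allclose(
            cmw, series_expm(_normalized_matrix(c.W)), atol=1e-9
        )

    def test_scale_invariance_of_normalized(self):
        c = random_connectome(9, 0.4, seed=11, weighted=True)
        cm1 = communicability_weighted(c, normalize=True).values
        cm2 = communicability_weighted(
            c.with_weights(c.W * 37.5), normalize=True
        ).values
        np.testing.assert_allclose(cm1, cm2, atol=1e-12)

    def test_cross_component_entries_exactly_zero(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        cm = communicability_binary(make_connectome(W)).values
        assert cm[0, 2] == 0.0 and cm[1, 3] == 0.0 and cm[0, 4] == 0.0


class TestNodeCommunicability:
    def test_k3_row_sum(self, k3):
        v = node_communicability(communicability_binary(k3))
        expected = 2 * (math.e**2 - math.exp(-1)) / 3.0
        np.testing.assert_allclose(v.values, expected, atol=1e-9)

    def test_empty_graph_zero(self, empty3):
        v = node_communicability(communicability_binary(empty3))
        np.testing.assert_array_equal(v.values, 0.0)

    def test_kind_mismatch_raises(self, path3):
        with pytest.raises(ValueError, match="communicability"):
            node_communicability(distance_matrix(path3))


class TestCommunicabilityCentrality:
    def test_star_center_is_one(self, star5):
        cbc = communicability_centrality(star5).values
        assert cbc[0] == pytest.approx(1.0, abs=1e-9)

    def test_path3_middle_is_one(self, path3):
        cbc = communicability_centrality(path3).values
        assert cbc[1] == pytest.approx(1.0, abs=1e-9)

    def test_isolated_node_is_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        cbc = communicability_centrality(make_connectome(W)).values
        assert cbc[3] == 0.0

    def test_too_few_nodes_raises(self, single_edge):
        with pytest.raises(ValueError, match="3 nodes"):
            communicability_centrality(single_edge)

    @pytest.mark.parametrize("seed", range(25))
    def test_bounded_on_random_graphs(self, seed):
        c = random_connectome(6 + seed % 10, 0.35, seed=100 + seed,
                              weighted=(seed % 2 == 1))
        for weighted in (False, True):
            cbc = communicability_centrality(c, weighted=weighted).values
            assert np.all(cbc >= 0.0) and np.all(cbc <= 1.0)

    def test_absolute_variant_unbounded_but_nonnegative(self, star5):
        cbc = communicability_centrality(star5, relative=False).values
        assert np.all(cbc >= 0.0)


class TestStandardMetrics:
    def test_degree_strength_single_edge(self):
        c = make_connectome([[0, 2.5], [2.5, 0]])
        deg, sw = degree_strength(c)
        np.testing.assert_array_equal(deg.values, [1, 1])
        np.testing.assert_allclose(sw.values, [2.5, 2.5])

    def test_degree_k3(self, k3):
        deg, _ = degree_strength(k3)
        np.testing.assert_array_equal(deg.values, [2, 2, 2])

    def test_binary_distance_path3(self, path3):
        d = distance_matrix(path3).values
        assert d[0, 2] == 2.0

    def test_weighted_distance_reciprocal_lengths(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 4.0
        W[1, 2] = W[2, 1] = 4.0
        d = distance_matrix(make_connectome(W), weighted=True).values
        assert d[0, 2] == pytest.approx(0.5)

    def test_disconnected_pairs_are_inf(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        d = distance_matrix(make_connectome(W)).values
        assert math.isinf(d[0, 2])

    def test_betweenness_path3(self, path3):
        bc = betweenness(path3).values
        np.testing.assert_allclose(bc, [0, 1, 0])

    def test_betweenness_k3_zero(self, k3):
        np.testing.assert_allclose(betweenness(k3).values, 0.0)

    def test_betweenness_star_center(self, star5):
        assert betweenness(star5).values[0] == pytest.approx(10.0)  # C(5,2)

    @pytest.mark.parametrize("seed", range(8))
    def test_betweenness_matches_brute_force(self, seed):
        c = random_connectome(5 + seed % 3, 0.5, seed=200 + seed,
                              weighted=(seed % 2 == 0))
        for weighted in (False, True):
            got = betweenness(c, weighted=weighted).values
            np.testing.assert_allclose(
                got, brute_betweenness(c, weighted=weighted), atol=1e-9
            )

    def test_efficiency_complete_graph(self, k4):
        assert global_efficiency(k4) == pytest.approx(1.0)

    def test_efficiency_path3(self, path3):
        assert global_efficiency(path3) == pytest.approx(5.0 / 6.0, abs=1e-9)

    def test_efficiency_empty_graph(self, empty3):
        assert global_efficiency(empty3) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_efficiency_bounds_and_edge_removal_monotone(self, seed):
        c = random_connectome(10, 0.3, seed=300 + seed)
        eff = global_efficiency(c)
        assert 0.0 <= eff <= 1.0
        ii, jj = np.nonzero(np.triu(c.W, 1))
        k = seed % len(ii)
        W = c.W.copy()
        W[ii[k], jj[k]] = W[jj[k], ii[k]] = 0.0
        assert global_efficiency(c.with_weights(W)) <= eff + 1e-12

    def test_cpl_path3(self, path3):
        cpl, frac = characteristic_path_length(path3)
        assert cpl == pytest.approx(4.0 / 3.0)
        assert frac == 0.0

    def test_cpl_complete_graph(self, k4):
        cpl, _ = characteristic_path_length(k4)
        assert cpl == pytest.approx(1.0)

    def test_cpl_fully_disconnected_raises(self):
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(make_connectome(np.zeros((2, 2))))


class TestHubs:
    def _with_degrees(self, degs):
        """Star-like graph with node 0 of degree degs[0]... uses explicit W."""
        return None

    def test_dominant_node_is_hub(self):
        # degrees (3, 1, 1, 1): mean 1.5, sample sd 1, threshold 2.5
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        assert identify_hubs(make_connectome(W)) == {0}

    def test_regular_graph_all_hubs(self, k3):
        assert identify_hubs(k3) == {0, 1, 2}

    def test_no_hubs_when_threshold_exceeds_max(self):
        # degrees (3, 3, 2, 2): mean 2.5, sd ~0.577 -> threshold ~3.08
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]:
            W[i, j] = W[j, i] = 1.0
        assert identify_hubs(make_connectome(W)) == set()

    def test_hemisphere_filter_applied_after_threshold(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        c = make_connectome(W, hemisphere=["L", "R", "R", "R"])
        assert identify_hubs(c, hemisphere_filter="R") == set()
        assert identify_hubs(c, hemisphere_filter="L") == {0}


class TestAssortativityAndDensity:
    def test_sorted_input_identity_permutation(self, path3):
        # degrees (1, 2, 1): stable ascending order (0, 2, 1)
        _, _, order = communicability_assortativity(path3)
        assert order.tolist() == [0, 2, 1]

    def test_star_cross_exceeds_bottom_block(self, star5):
        _, summary, _ = communicability_assortativity(star5, k=1)
        assert summary["cross"] > summary["bottom"]

    def test_empty_graph_blocks_zero(self, empty3):
        _, summary, _ = communicability_assortativity(empty3, normalize=False)
        assert summary["top"] == 0.0 and summary["cross"] == 0.0

    def test_top_density_triangle(self, k3):
        deg, _ = degree_strength(k3)
        assert top_node_density(k3, deg, 3) == 1.0

    def test_top_density_no_edges(self, empty3):
        deg, _ = degree_strength(empty3)
        assert top_node_density(empty3, deg, 3) == 0.0

    def test_top_density_half(self):
        # 4 nodes, edges (0-1, 1-2, 2-3): 3 of 6 possible
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        c = make_connectome(W)
        deg, _ = degree_strength(c)
        assert top_node_density(c, deg, 4) == pytest.approx(0.5)

    def test_k_out_of_range(self, k3):
        deg, _ = degree_strength(k3)
        with pytest.raises(ValueError, match="out of range"):
            top_node_density(k3, deg, 5)


class TestMetricTable:
    def test_columns_and_shapes(self, tiny_cohort):
        c = tiny_cohort.subjects[0][1]
        df = node_metric_table(c)
        assert list(df.columns) == ["Deg", "Sw", "BC", "BCw", "Cm", "Cmw",
                                    "CBC", "CBCw"]
        assert len(df) == c.n_nodes
        assert df["CBC"].between(0, 1).all()
        assert df["CBCw"].between(0, 1).all()
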