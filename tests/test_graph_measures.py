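import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from oracles import (
    clustering_oracle,
    degree_oracle,
    floyd_warshall_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
)
from tdcsgraph.connectome import ConnectivityMatrix, ThresholdedGraph, density_sweep
from tdcsgraph.graph_measures import (
    clustering,
    degree,
    global_efficiency,
    local_efficiency,
    measure_vector,
    path_length,
    rewire_null,
    shortest_paths,
    site_measures,
    small_worldness,
    synthetic_site_map,
)

TRIANGLE = ThresholdedGraph(
    np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float), 1.0
)
CHAIN = ThresholdedGraph(
    np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float), 0.67
)


class TestSmallGraphValues:
    def test_unit_triangle(self):
        assert np.allclose(degree(TRIANGLE), [2, 2, 2])
        c_local, c_net = clustering(TRIANGLE)
        assert np.allclose(c_local, 1.0) and c_net == 1.0
        assert np.allclose(local_efficiency(TRIANGLE), 1.0)

    def test_star_has_no_triangles(self):
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        _, c_net = clustering(ThresholdedGraph(star, 0.5))
        assert c_net == 0.0

    def test_unit_chain_path_lengths(self):
        d = shortest_paths(CHAIN)
        assert d[0, 2] == 2.0
        _, l_net = path_length(CHAIN)
        assert l_net == pytest.approx(4 / 3)  # (1.5 + 1 + 1.5)/3
        assert global_efficiency(CHAIN) == pytest.approx(5 / 6)

    def test_half_weight_edge_doubles_length(self):
        two = np.array([[0, 0.5], [0.5, 0]])
        assert shortest_paths(two)[0, 1] == 2.0

    def test_complete_graph_unit_everything(self):
        k4 = ThresholdedGraph(np.ones((4, 4)) - np.eye(4), 1.0)
        _, l_net = path_length(k4)
        assert l_net == 1.0
        assert global_efficiency(k4) == 1.0

    def test_isolated_node_and_leaf(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = ThresholdedGraph(w, 0.33, connected=False)
        assert degree(g)[2] == 0.0
        assert local_efficiency(g)[0] == 0.0  # leaf: single neighbor
        assert global_efficiency(g) == pytest.approx(2 / 6)

    def test_edgeless_graph_zero_efficiency(self):
        g = ThresholdedGraph(np.zeros((4, 4)), 0.01, connected=False)
        assert global_efficiency(g) == 0.0


class TestOracleEquivalence:
    """Brute-force definitional oracles on random graphs, N <= 10."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_measures_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        w = random_weighted_graph(n, 0.5, rng, as_graph=False)
        g = ThresholdedGraph(w, 0.5, connected=True)

        assert np.allclose(degree(g), degree_oracle(w), atol=1e-10)

        c_local, c_net = clustering(g)
        oc_local, oc_net = clustering_oracle(w)
        assert np.allclose(c_local, oc_local, atol=1e-10)
        assert c_net == pytest.approx(oc_net, abs=1e-10)

        d = shortest_paths(g)
        od = floyd_warshall_oracle(w)
        assert np.allclose(d, od, atol=1e-10)

        assert global_efficiency(g) == pytest.approx(
            global_efficiency_oracle(w), abs=1e-10
        )
        assert np.allclose(
            local_efficiency(g), local_efficiency_oracle(w), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_onnela_clustering_matches_networkx(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(8, 0.6, rng, as_graph=False)
        G = nx.from_numpy_array(w)
        ref = nx.clustering(G, weight="weight")
        c_local, _ = clustering(w)
        for i in range(8):
            assert c_local[i] == pytest.approx(ref[i], abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_paths_match_networkx_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(9, 0.4, rng, as_graph=False)
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), 0.0)
        G = nx.from_numpy_array(lengths)
        ref = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
        d = shortest_paths(w)
        for i in range(9):
            for j in range(9):
                expected = ref[i].get(j, np.inf)
                assert d[i, j] == pytest.approx(expected, abs=1e-10) or (
                    np.isinf(d[i, j]) and np.isinf(expected)
                )


class TestSweepMonotonicity:
    def test_efficiency_up_paths_down_with_density(self, rng):
        z = np.triu(rng.normal(0.8, 0.2, (20, 20)), 1)
        z = z + z.T
        np.fill_diagonal(z, 0.0)
        graphs = density_sweep(ConnectivityMatrix(z), 0.3, 0.6, 0.05)
        e = [global_efficiency(g) for g in graphs]
        l = [path_length(g)[1] for g in graphs]
        assert all(b >= a - 1e-12 for a, b in zip(e, e[1:]))
        finite = [x for x in l if np.isfinite(x)]
        assert all(b <= a + 1e-12 for a, b in zip(finite, finite[1:]))


class TestScaleBehavior:
    def test_weight_scaling(self, rng):
        w = random_weighted_graph(8, 0.6, rng, as_graph=False)
        c = 3.7
        assert np.allclose(degree(c * w), c * degree_oracle(w))
        assert np.allclose(shortest_paths(c * w), shortest_paths(w) / c)
        # max-normalized clustering is scale-free
        assert np.allclose(clustering(c * w)[0], clustering(w)[0])


class TestRewiredNulls:
    def test_preserves_degree_sequence_and_weight_multiset(self, rng):
        from tdcsgraph.graph_measures import _rewire_edges

        w = random_weighted_graph(12, 0.4, rng, as_graph=False)
        null_w, _ = _rewire_edges(w, np.random.default_rng(3))
        assert np.array_equal((null_w > 0).sum(1), (w > 0).sum(1))
        iu = np.triu_indices(12, 1)
        assert np.allclose(np.sort(null_w[iu]), np.sort(w[iu]))
        assert np.allclose(null_w, null_w.T)
        assert np.all(np.diag(null_w) == 0)

    def test_deterministic_per_seed(self, rng):
        g = random_weighted_graph(10, 0.5, rng)
        assert rewire_null(g, n_nulls=5, seed=7) == \
            rewire_null(g, n_nulls=5, seed=7)

    def test_complete_graph_null_equals_graph(self):
        # no double-edge swap is acceptable on a complete graph, so every
        # null is the graph itself (the attempt budget warning is expected)
        k5 = ThresholdedGraph(np.ones((5, 5)) - np.eye(5), 1.0)
        with pytest.warns(RuntimeWarning):
            c_r, l_r = rewire_null(k5, n_nulls=3, seed=0)
        _, c_net = clustering(k5)
        _, l_net = path_length(k5)
        assert c_r == pytest.approx(c_net)
        assert l_r == pytest.approx(l_net)
        with pytest.warns(RuntimeWarning):
            assert small_worldness(k5, n_nulls=3, seed=0) == pytest.approx(1.0)

    def test_too_few_edges_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValueError):
            rewire_null(ThresholdedGraph(w, 0.1), n_nulls=2, seed=0)

    def test_sigma_composes_from_parts(self, rng):
        g = random_weighted_graph(12, 0.4, rng)
        c_r, l_r = rewire_null(g, n_nulls=10, seed=5)
        _, c_net = clustering(g)
        _, l_net = path_length(g)
        expected = (c_net / c_r) / (l_net / l_r)
        assert small_worldness(g, n_nulls=10, seed=5) == pytest.approx(expected)


class TestSiteMeasures:
    NODAL = {"L_local": np.array([1.4, 1.0, 2.0, 3.0])}

    def test_single_mapped_node(self):
        out = site_measures(self.NODAL, {"F7": [0]}, ["F7"])
        assert out["L_local"] == 1.4

    def test_mean_over_mapped_nodes(self):
        out = site_measures(self.NODAL, {"F7": [1, 2]}, ["F7"])
        assert out["L_local"] == 1.5

    def test_two_electrodes_pool_all_nodes(self):
        sites = {"F7": [1, 2], "F8": [3]}
        out = site_measures(self.NODAL, sites, ["F7", "F8"])
        assert out["L_local"] == pytest.approx((1.0 + 2.0 + 3.0) / 3)

    def test_unmapped_electrode_named(self):
        with pytest.raises(KeyError, match="CP6"):
            site_measures(self.NODAL, {"F7": [0]}, ["CP6"])

    def test_synthetic_map_covers_all_labels(self):
        m = synthetic_site_map(["F7", "F8", "CP6"], 10)
        assert set(m) == {"F7", "F8", "CP6"}
        assert all(0 <= i < 10 for v in m.values() for i in v)


class TestMeasureVector:
    def test_collects_all_measures(self, rng):
        g = random_weighted_graph(10, 0.5, rng)
        mv = measure_vector(
            g, sites={"F7": [0, 1]}, electrodes=["F7"], n_nulls=3, seed=1
        )
        assert set(mv.globals_dict()) == {"C_net", "L_net", "E_net", "sigma"}
        assert set(mv.site) == {"K", "C_local", "L_local", "E_local"}
        assert mv.site["K"] == pytest.approx(degree(g)[:2].mean())

    def test_sigma_skippable(self, rng):
        g = random_weighted_graph(10, 0.5, rng)
        mv = measure_vector(g, compute_sigma=False)
        assert np.isnan(mv.sigma)
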