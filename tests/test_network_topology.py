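import numpy as np
import pytest

import _graph_oracle as oracle
from swaynet.network_topology import (SparsityGrid, clustering_and_pathlength,
                                      global_efficiency, is_connected,
                                      local_efficiency, metric_auc,
                                      min_connected_sparsity,
                                      n_edges_at_sparsity, network_metrics,
                                      nodal_efficiency, rewire_degree_preserving,
                                      ring_lattice, shortest_path_lengths,
                                      small_worldness, threshold_proportional)
from swaynet.roi_connectivity import FcMatrix


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


K4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
STAR4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
TWO_EDGES = adj_from_edges(4, [(0, 1), (2, 3)])


def fc_from_weights(z):
    z = np.asarray(z, float)
    z = np.triu(z, 1)
    z = z + z.T
    return FcMatrix(z=z)


def random_fc(rng, n=10):
    z = np.abs(rng.standard_normal((n, n)))
    return fc_from_weights(z)


class TestDistances:
    def test_complete_graph_all_one(self):
        d = shortest_path_lengths(K4)
        off = ~np.eye(4, dtype=bool)
        assert (d[off] == 1).all()

    def test_path_two_hops(self):
        assert shortest_path_lengths(PATH3)[0, 2] == 2

    def test_disconnected_infinite(self):
        d = shortest_path_lengths(TWO_EDGES)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


class TestEfficiencies:
    def test_global_complete(self):
        assert global_efficiency(K4) == pytest.approx(1.0)

    def test_global_path(self):
        assert global_efficiency(PATH3) == pytest.approx(5 / 6)

    def test_global_two_disjoint_edges(self):
        assert global_efficiency(TWO_EDGES) == pytest.approx(1 / 3)

    def test_local_complete(self):
        assert local_efficiency(K4) == pytest.approx(1.0)

    def test_local_path_and_star_zero(self):
        assert local_efficiency(PATH3) == 0.0
        assert local_efficiency(STAR4) == 0.0

    def test_nodal_star(self):
        ne = nodal_efficiency(STAR4)
        assert ne[0] == pytest.approx(1.0)  # hub
        assert ne[1] == pytest.approx(2 / 3)  # leaf: 1 + 1/2 + 1/2 over 3

    def test_nodal_isolated_zero(self):
        a = adj_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert nodal_efficiency(a)[3] == 0.0


class TestClusteringPathlength:
    def test_complete(self):
        assert clustering_and_pathlength(K4) == (1.0, 1.0)

    def test_ring_lattice_half(self):
        c, _ = clustering_and_pathlength(ring_lattice(10, 4))
        assert c == pytest.approx(0.5)

    def test_path(self):
        c, l = clustering_and_pathlength(PATH3)
        assert c == 0.0
        assert l == pytest.approx(4 / 3)

    def test_no_edges_raises(self):
        with pytest.raises(ValueError):
            clustering_and_pathlength(np.zeros((3, 3), dtype=bool))


class TestOracleEquivalence:
    """Engine vs brute-force oracle on random small graphs."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(3, 11))
            p = rng.uniform(0.1, 0.9)
            a = rng.random((n, n)) < p
            a = np.triu(a, 1)
            a = a | a.T
            assert global_efficiency(a) == pytest.approx(
                oracle.global_efficiency(a), abs=1e-12)
            assert local_efficiency(a) == pytest.approx(
                oracle.local_efficiency(a), abs=1e-12)
            assert np.allclose(nodal_efficiency(a),
                               oracle.nodal_efficiency(a), atol=1e-12)
            c, _ = (clustering_and_pathlength(a)
                    if a.any() else (0.0, None))
            if a.any():
                assert c == pytest.approx(oracle.clustering(a), abs=1e-12)


class TestThresholding:
    def test_edge_count_at_min_sparsity(self):
        assert n_edges_at_sparsity(0.2667) == 12

    def test_full_sparsity_complete(self, rng):
        adj = threshold_proportional(random_fc(rng), 1.0)
        assert adj.sum() // 2 == 45

    def test_nestedness_over_grid(self, rng):
        fc = random_fc(rng)
        grid = SparsityGrid()
        prev = None
        for s in grid.thresholds:
            adj = threshold_proportional(fc, s)
            if prev is not None:
                assert (adj | prev == adj).all()  # prev's edges kept
            prev = adj

    def test_too_few_positive_edges_raises(self):
        z = np.zeros((10, 10))
        z[0, 1] = 1.0
        with pytest.raises(ValueError):
            threshold_proportional(fc_from_weights(z), 0.2667)


class TestSparsityGrid:
    def test_default_grid(self):
        grid = SparsityGrid()
        t = grid.thresholds
        assert t.size == 24
        assert t[0] == pytest.approx(0.2667)
        assert t[-1] == pytest.approx(0.4967)

    def test_auc_constant_curve(self):
        assert metric_auc(np.ones(24), 0.01) == pytest.approx(0.24)

    def test_auc_linearity(self, rng):
        curve = rng.random(24)
        assert metric_auc(3 * curve) == pytest.approx(3 * metric_auc(curve))


class TestMinConnectedSparsity:
    @staticmethod
    def ranked_fc(edge_ranks, n=10):
        """FC whose k-th listed edge has the k-th largest weight."""
        z = np.zeros((n, n))
        w = 100.0
        for i, j in edge_ranks:
            z[i, j] = w
            w -= 1.0
        return fc_from_weights(z)

    def test_spanning_tree_nine_edges(self):
        tree = [(i, i + 1) for i in range(9)]
        fc = self.ranked_fc(tree)
        assert min_connected_sparsity([fc]) == pytest.approx(9 / 45)

    def test_isolated_node_until_twelfth_edge(self):
        # 11 strong edges connect nodes 0..8; node 9 joins via rank 12
        edges = [(i, i + 1) for i in range(8)]  # path over 0..8
        edges += [(0, 2), (0, 3), (0, 4)]  # 3 redundant strong edges
        edges += [(8, 9)]  # rank 12 attaches node 9
        fc = self.ranked_fc(edges)
        assert min_connected_sparsity([fc]) == pytest.approx(12 / 45)
        assert 12 / 45 == pytest.approx(0.2667, abs=1e-4)

    def test_max_over_participants(self):
        need10 = [(i, i + 1) for i in range(8)] + [(0, 2), (8, 9)]
        need13 = ([(i, i + 1) for i in range(8)]
                  + [(0, 2), (0, 3), (0, 4), (0, 5), (8, 9)])
        fcs = [self.ranked_fc(need10), self.ranked_fc(need13)]
        assert min_connected_sparsity(fcs) == pytest.approx(13 / 45)

    def test_unconnectable_names_participant(self):
        z = np.zeros((10, 10))
        z[0, 1] = 1.0
        with pytest.raises(ValueError, match="p7"):
            min_connected_sparsity([self.ranked_fc([(0, 1)])], labels=["p7"])


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for seed in range(20):
            a = (lambda m: m | m.T)(np.triu(rng.random((12, 12)) < 0.4, 1))
            if a.sum() < 4:
                continue
            null = rewire_degree_preserving(a, seed=seed,
                                            require_connected=False)
            assert (null.sum(axis=0) == a.sum(axis=0)).all()
            assert null.sum() == a.sum()

    def test_lattice_nulls_lose_clustering(self):
        lat = ring_lattice(20, 4)
        cs = []
        for seed in range(100):
            null = rewire_degree_preserving(lat, seed=seed)
            c, _ = clustering_and_pathlength(null)
            cs.append(c)
        assert np.mean(cs) < 0.5


class TestSmallWorldness:
    def test_complete_graph_exactly_one(self):
        k10 = ~np.eye(10, dtype=bool)
        assert small_worldness(k10, n_rand=200, seed=0) == 1.0

    def test_watts_strogatz_above_one(self):
        import networkx as nx
        g = nx.watts_strogatz_graph(20, 4, 0.1, seed=42)
        sigma = small_worldness(nx.to_numpy_array(g, dtype=bool),
                                n_rand=200, seed=1)
        assert sigma > 1.0

    def test_null_members_self_normalize_on_average(self):
        # a single 10-node draw has large sigma spread (member clustering
        # ranges ~0.15-0.5), so the calibration check is on the ensemble mean
        sigmas = [small_worldness(rewire_degree_preserving(ring_lattice(10, 4),
                                                           seed=s),
                                  n_rand=300, seed=1000 + s)
                  for s in range(20)]
        assert 0.8 <= np.mean(sigmas) <= 1.25

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError):
            small_worldness(TWO_EDGES, n_rand=10, seed=0)

    def test_seeded_reproducibility(self):
        g = ring_lattice(10, 4)
        assert small_worldness(g, n_rand=100, seed=3) == \
            small_worldness(g, n_rand=100, seed=3)


class TestNetworkMetrics:
    def test_equal_weights_bounded_curves(self):
        fc = fc_from_weights(np.full((10, 10), 2.0))
        mset = network_metrics(fc, n_rand=50, seed=0, return_curves=True)
        assert ((mset.curves["Eg"] > 0) & (mset.curves["Eg"] <= 1)).all()
        assert mset.eg_auc <= SparsityGrid().width + 1e-12
        assert mset.ne_auc.shape == (10,)

    def test_disconnected_at_min_mentions_remedy(self):
        # two 5-cliques: 20 strong internal edges, no bridge in the top 12
        z = np.zeros((10, 10))
        for grp in (range(5), range(5, 10)):
            for i in grp:
                for j in grp:
                    if i < j:
                        z[i, j] = 5.0
        z[0, 5] = 0.1
        with pytest.raises(ValueError, match="min_connected_sparsity"):
            network_metrics(fc_from_weights(z), n_rand=10, seed=0)
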