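import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from oracles import best_partition_q, modularity_from_definition
from subcomplex.mmc import (
    MaxModularityClustering,
    delta_merge,
    delta_move,
    merge_tree_newick,
    mmc_cluster,
    modularity,
    total_weight,
)


def cluster_dev(net, cluster):
    deg = dict(net.degree(weight="weight"))
    return sum(deg[v] for v in cluster)


def between_weight(net, c1, c2):
    return sum(
        d.get("weight", 1.0)
        for u, v, d in net.edges(data=True)
        if (u in c1 and v in c2) or (u in c2 and v in c1)
    )


class TestModularity:
    def test_single_cluster_is_zero(self, two_triangles):
        assert modularity(two_triangles, [list(two_triangles.nodes)]) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_true_partition(self, two_triangles):
        q = modularity(two_triangles, [[0, 1, 2], [3, 4, 5]])
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_all_singletons(self, two_triangles):
        q = modularity(two_triangles, [[v] for v in two_triangles.nodes])
        assert q == pytest.approx(-6 * 4 / 144, abs=1e-12)  # -1/6

    def test_edgeless_graph_rejected(self):
        net = nx.Graph()
        net.add_nodes_from([1, 2])
        with pytest.raises(ValueError, match="edgeless"):
            modularity(net, [[1], [2]])

    def test_non_partition_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            modularity(two_triangles, [[0, 1, 2]])

    def test_matches_definition_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            net = random_graph(rng)
            nodes = list(net.nodes)
            labels = rng.integers(0, 3, size=len(nodes))
            parts = [
                [v for v, l in zip(nodes, labels) if l == k] for k in range(3)
            ]
            parts = [p for p in parts if p]
            assert modularity(net, parts) == pytest.approx(
                modularity_from_definition(net, parts), abs=1e-12
            )


class TestDeltaMerge:
    def test_merging_the_two_triangles(self, two_triangles):
        f_vv = total_weight(two_triangles)
        dq = delta_merge(0.0, 6.0, 6.0, f_vv)
        assert dq == pytest.approx(-0.5, abs=1e-12)  # Q goes 0.5 -> 0

    def test_two_vertex_graph_single_edge(self):
        net = nx.Graph([(0, 1)])
        dq = delta_merge(1.0, 1.0, 1.0, total_weight(net))
        assert dq == pytest.approx(0.5, abs=1e-12)

    def test_disconnected_clusters_never_gain(self):
        # first term zero, second strictly negative for positive degrees
        assert delta_merge(0.0, 3.0, 5.0, 40.0) < 0

    def test_equals_from_scratch_difference_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_graph(rng)
            nodes = list(net.nodes)
            if len(nodes) < 3:
                continue
            labels = rng.integers(0, 3, size=len(nodes))
            parts = [
                [v for v, l in zip(nodes, labels) if l == k] for k in range(3)
            ]
            parts = [p for p in parts if p]
            if len(parts) < 2:
                continue
            c1, c2 = parts[0], parts[1]
            merged = [c1 + c2] + parts[2:]
            expected = modularity_from_definition(
                net, merged
            ) - modularity_from_definition(net, parts)
            dq = delta_merge(
                between_weight(net, c1, c2),
                cluster_dev(net, c1),
                cluster_dev(net, c2),
                total_weight(net),
            )
            assert dq == pytest.approx(expected, abs=1e-12)


class TestDeltaMove:
    def test_identity_move_is_zero(self):
        assert delta_move(2.0, 2.0, 3.0, 5.0, 5.0, 20.0) == pytest.approx(0.0)

    def test_degree_zero_vertex_moves_freely(self):
        assert delta_move(0.0, 0.0, 0.0, 4.0, 2.0, 20.0) == pytest.approx(0.0)

    def test_equals_from_scratch_difference_on_random_graphs(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            net = random_graph(rng)
            nodes = list(net.nodes)
            if len(nodes) < 3:
                continue
            labels = rng.integers(0, 3, size=len(nodes))
            parts = [
                set(v for v, l in zip(nodes, labels) if l == k) for k in range(3)
            ]
            parts = [p for p in parts if p]
            if len(parts) < 2:
                continue
            ci, cj = parts[0], parts[1]
            v = sorted(ci)[0]
            moved = [ci - {v}, cj | {v}] + parts[2:]
            moved = [p for p in moved if p]
            expected = modularity_from_definition(
                net, moved
            ) - modularity_from_definition(net, parts)
            dq = delta_move(
                between_weight(net, {v}, cj),
                between_weight(net, {v}, ci - {v}),
                cluster_dev(net, {v}),
                cluster_dev(net, cj),
                cluster_dev(net, ci) - cluster_dev(net, {v}),
                total_weight(net),
            )
            assert dq == pytest.approx(expected, abs=1e-12)
            checked += 1


def ring_of_cliques(n_cliques=4, clique_size=4):
    net = nx.Graph()
    for k in range(n_cliques):
        base = k * clique_size
        for i in range(clique_size):
            for j in range(i + 1, clique_size):
                net.add_edge(base + i, base + j)
    for k in range(n_cliques):
        net.add_edge(k * clique_size, ((k + 1) % n_cliques) * clique_size + 1)
    return net


class TestMmcCluster:
    def test_bridged_triangles_split_at_the_bridge(self):
        net = nx.Graph(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
        result = mmc_cluster(net)
        assert set(result.clusters) == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }
        best_q, _ = best_partition_q(net)
        assert result.modularity == pytest.approx(best_q, abs=1e-12)

    def test_complete_graph_collapses_to_one_cluster(self):
        result = mmc_cluster(nx.complete_graph(5))
        assert len(result.clusters) == 1

    def test_ring_of_cliques_recovers_the_cliques(self):
        result = mmc_cluster(ring_of_cliques())
        expected = {
            frozenset(range(k * 4, k * 4 + 4)) for k in range(4)
        }
        assert set(result.clusters) == expected

    def test_q_trace_is_strictly_increasing(self, two_triangles):
        net = two_triangles.copy()
        net.add_edge(2, 3)
        result = mmc_cluster(net)
        trace = result.q_trace
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_edgeless_graph_gives_singletons_with_undefined_q(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        result = mmc_cluster(net)
        assert len(result.clusters) == 3
        assert result.modularity is None

    def test_final_q_beats_trivial_partitions(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_graph(rng)
            result = mmc_cluster(net)
            singles = modularity_from_definition(net, [[v] for v in net.nodes])
            assert result.modularity >= max(singles, 0.0) - 1e-12

    def test_cached_q_matches_recomputation(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            net = random_graph(rng)
            result = mmc_cluster(net)
            assert result.modularity == pytest.approx(
                modularity_from_definition(net, result.clusters), abs=1e-12
            )

    def test_merge_tree_newick_covers_all_vertices(self, two_triangles):
        result = mmc_cluster(two_triangles)
        nwk = merge_tree_newick(result, two_triangles.nodes)
        for v in two_triangles.nodes:
            assert str(v) in nwk
        assert nwk.endswith(";")


class TestEstimator:
    def test_fit_on_adjacency_matrix(self, two_triangles):
        a = nx.to_numpy_array(two_triangles)
        est = MaxModularityClustering().fit(a)
        labels = est.labels_
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]
        assert est.modularity_ == pytest.approx(0.5, abs=1e-12)
        assert est.n_clusters_ == 2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            MaxModularityClustering().fit(np.array([[0, 1], [0, 0]]))
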