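import numpy as np
import networkx as nx
import pytest

from calcinet import (
    CellTable,
    ConnectivityMatrix,
    build_graph,
    clustering_coefficient,
    degree_stats,
    detect_communities,
    global_efficiency,
    modularity,
)
from _oracles import (
    best_modularity_partition,
    clustering_brute,
    efficiency_brute,
    modularity_brute,
)


def cmat(rho, ids=None):
    rho = np.asarray(rho, float)
    n = rho.shape[0]
    ids = ids or [f"c{i}" for i in range(n)]
    return ConnectivityMatrix(
        rho_max=rho,
        best_lag=np.zeros((n, n), dtype=int),
        lag_set=np.array([-1, 0, 1]),
        cell_ids=ids,
    )


class TestBuildGraph:
    def test_threshold_keeps_strong_edges_only(self):
        rho = np.array([[1, 0.7, 0.5], [0.7, 1, 0.2], [0.5, 0.2, 1]])
        g = build_graph(cmat(rho), theta=0.6)
        assert g.n_edges == 1
        assert g.graph.has_edge("c0", "c1")
        assert g.n_nodes == 3  # isolated nodes retained

    def test_none_threshold_keeps_all_pairs(self):
        rho = np.array([[1, 0.7, 0.5], [0.7, 1, 0.2], [0.5, 0.2, 1]])
        g = build_graph(cmat(rho), theta=None)
        assert g.n_edges == 3

    def test_boundary_is_inclusive(self):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        g = build_graph(cmat(rho), theta=1.0)
        assert g.n_edges == 1

    def test_raising_theta_never_adds_edges(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8))
        rho = (a + a.T) / 2
        np.fill_diagonal(rho, 1.0)
        edges = [
            build_graph(cmat(rho), theta=t).n_edges
            for t in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(x >= y for x, y in zip(edges, edges[1:]))

    def test_node_attributes_from_cell_table(self):
        rho = np.array([[1, 0.9], [0.9, 1]])
        cells = CellTable(
            x=np.array([1.0, 2.0]), y=np.array([3.0, 4.0]),
            cell_ids=["c0", "c1"], labels=["RFP", None],
        )
        g = build_graph(cmat(rho), theta=0.3, cells=cells)
        assert g.graph.nodes["c0"] == {"x": 1.0, "y": 3.0, "label": "RFP"}
        assert "label" not in g.graph.nodes["c1"]

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            build_graph(cmat(np.eye(2)), theta=1.5)


class TestDegreeStats:
    def test_triangle(self, make_graph):
        g = make_graph(3, [(0, 1), (1, 2), (0, 2)])
        out = degree_stats(g)
        assert list(out.degrees.values()) == [2, 2, 2]
        assert out.mean_degree == 2.0

    def test_edgeless(self, make_graph):
        out = degree_stats(make_graph(4, []))
        assert all(d == 0 for d in out.degrees.values())
        assert out.mean_degree == 0.0

    def test_handshake_recount(self, make_graph):
        rng = np.random.default_rng(1)
        edges = [
            (i, j) for i in range(8) for j in range(i + 1, 8)
            if rng.random() < 0.4
        ]
        out = degree_stats(make_graph(8, edges))
        assert sum(out.degrees.values()) == 2 * len(edges)
        assert out.mean_degree == pytest.approx(2 * len(edges) / 8)


class TestClusteringCoefficient:
    def test_complete_graph(self, make_graph):
        k4 = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        assert clustering_coefficient(make_graph(4, k4)) == 1.0

    def test_path_has_no_triangles(self, make_graph):
        assert clustering_coefficient(make_graph(3, [(0, 1), (1, 2)])) == 0.0

    def test_triangle_plus_pendant(self, make_graph):
        g = make_graph(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        # node 0: k=3, e=1 -> 1/3; nodes 1,2: 1; node 3 excluded (k=1)
        assert clustering_coefficient(g) == pytest.approx(7 / 9)

    def test_count_low_degree_as_zero_variant(self, make_graph):
        g = make_graph(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        assert clustering_coefficient(
            g, count_low_degree_as_zero=True
        ) == pytest.approx((1 / 3 + 1 + 1 + 0) / 4)

    def test_no_qualifying_node_returns_zero(self, make_graph):
        assert clustering_coefficient(make_graph(2, [(0, 1)])) == 0.0

    def test_random_graphs_match_brute_force(self, make_graph):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            edges = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.45
            ]
            g = make_graph(n, edges)
            assert clustering_coefficient(g) == pytest.approx(
                clustering_brute(n, edges), abs=1e-12
            )


class TestGlobalEfficiency:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_complete_graph_is_one(self, make_graph, n):
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert global_efficiency(make_graph(n, edges)) == pytest.approx(1.0)

    def test_path_three_nodes(self, make_graph):
        g = make_graph(3, [(0, 1), (1, 2)])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_two_disconnected_edges(self, make_graph):
        g = make_graph(4, [(0, 1), (2, 3)])
        assert global_efficiency(g) == pytest.approx(1 / 3)

    def test_single_node_rejected(self, make_graph):
        with pytest.raises(ValueError):
            global_efficiency(make_graph(1, []))

    def test_random_graphs_match_brute_force(self, make_graph):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            edges = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.35
            ]
            g = make_graph(n, edges)
            assert global_efficiency(g) == pytest.approx(
                efficiency_brute(n, edges), abs=1e-12
            )


TWO_TRIANGLES = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]


class TestCommunities:
    def test_two_triangle_bridge_graph(self, make_graph):
        g = make_graph(6, TWO_TRIANGLES)
        part = detect_communities(g)
        memb = [part.membership[str(i)] for i in range(6)]
        assert memb[0] == memb[1] == memb[2]
        assert memb[3] == memb[4] == memb[5]
        assert memb[0] != memb[3]
        assert part.modularity == pytest.approx(5 / 14, abs=1e-9)

    def test_two_triangle_partition_is_exhaustively_optimal(self, make_graph):
        best_q, _ = best_modularity_partition(6, TWO_TRIANGLES)
        part = detect_communities(make_graph(6, TWO_TRIANGLES))
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_single_clique_never_splits(self, make_graph):
        k4 = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        part = detect_communities(make_graph(4, k4))
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_singletons(self, make_graph):
        part = detect_communities(make_graph(5, []))
        assert part.n_communities == 5
        assert part.modularity == 0.0

    def test_planted_two_block_graph_recovered(self, make_graph):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        truth = [0] * 10 + [1] * 10
        edges = []
        for i in range(20):
            for j in range(i + 1, 20):
                p = 0.9 if truth[i] == truth[j] else 0.05
                if rng.random() < p:
                    edges.append((i, j))
        part = detect_communities(make_graph(20, edges))
        memb = [part.membership[str(i)] for i in range(20)]
        assert adjusted_rand_score(truth, memb) == 1.0

    def test_reported_q_matches_direct_formula_on_random_graphs(
        self, make_graph
    ):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 14))
            edges = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            part = detect_communities(make_graph(n, edges))
            memb = [part.membership[str(i)] for i in range(n)]
            assert part.modularity == pytest.approx(
                modularity_brute(n, edges, memb), abs=1e-9
            )

    def test_determinism(self, make_graph):
        rng = np.random.default_rng(6)
        edges = [
            (i, j) for i in range(15) for j in range(i + 1, 15)
            if rng.random() < 0.3
        ]
        a = detect_communities(make_graph(15, edges))
        b = detect_communities(make_graph(15, edges))
        assert a.membership == b.membership
        assert a.modularity == b.modularity

    def test_matches_igraph_leading_eigenvector_quality(self, make_graph):
        """Independent cross-check: on clean community structure the
        partition and its modularity agree with igraph's implementation."""
        import igraph as ig

        g_ours = detect_communities(make_graph(6, TWO_TRIANGLES))
        g_ig = ig.Graph(6, TWO_TRIANGLES)
        cl = g_ig.community_leading_eigenvector()
        assert g_ig.modularity(cl) == pytest.approx(
            g_ours.modularity, abs=1e-9
        )
        assert sorted(len(c) for c in cl) == sorted(
            np.bincount(
                [g_ours.membership[str(i)] for i in range(6)]
            ).tolist()
        )

    def test_disconnected_components_never_share_community(self, make_graph):
        g = make_graph(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        part = detect_communities(g)
        memb = part.membership
        assert {memb["0"], memb["1"], memb["2"]}.isdisjoint(
            {memb["3"], memb["4"], memb["5"]}
        )

    def test_large_community_count_threshold(self, make_graph):
        # one 6-clique (large: > 5 members) and one triangle (not large)
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        edges += [(6, 7), (7, 8), (6, 8)]
        part = detect_communities(make_graph(9, edges))
        assert part.large_community_count == 1


def test_modularity_direct_evaluator_edge_cases():
    adj = np.zeros((3, 3))
    assert modularity(adj, np.array([0, 1, 2])) == 0.0
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    q = modularity(adj, np.array([0, 0, 1]))
    assert q == pytest.approx(modularity_brute(3, [(0, 1), (1, 2)], [0, 0, 1]))
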