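"""Graph core: SPDM, BFS balls, closeness, origin selection, sampling."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netcoherence import (
    SpatialGraph,
    ball_growth,
    bfs_ball,
    closeness_centrality,
    sample_subgraph,
    select_central_origins,
    shortest_path_matrix,
)
from netcoherence.graph import largest_component, origin_count

from .conftest import grid_graph, random_connected_graph


class TestSpatialGraph:
    def test_rejects_self_loops_and_duplicates(self):
        with pytest.raises(ValueError, match="self-loop"):
            SpatialGraph.from_edges(3, [[0, 0]])
        with pytest.raises(ValueError, match="duplicate"):
            SpatialGraph.from_edges(3, [[0, 1], [1, 0]])

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError, match="positive"):
            SpatialGraph.from_edges(2, [[0, 1]], weights=[0.0])

    def test_rejects_intra_part_edges(self):
        with pytest.raises(ValueError, match="intra-part"):
            SpatialGraph.from_edges(3, [[0, 1]], part_labels=[0, 0, 1])

    def test_canonicalization_carries_weights(self):
        g = SpatialGraph.from_edges(3, [[2, 0], [1, 0]], weights=[5.0, 7.0])
        assert g.edges.tolist() == [[0, 1], [0, 2]]
        assert g.weights.tolist() == [7.0, 5.0]

    def test_subgraph_is_induced(self):
        g, G = random_connected_graph(15, 0.3, seed=2)
        nodes = [1, 3, 4, 7, 9]
        sub, old = g.subgraph(nodes)
        expected = {
            (min(a, b), max(a, b))
            for a, b in G.edges()
            if a in nodes and b in nodes
        }
        got = {(old[u], old[v]) for u, v in sub.edges}
        got = {(min(a, b), max(a, b)) for a, b in got}
        assert got == expected


class TestShortestPathMatrix:
    def test_path_graph_hops(self, path5):
        m = shortest_path_matrix(path5, "hop").matrix
        assert m[0, 2] == 2
        assert np.all(np.diag(m) == 0)
        assert np.array_equal(m, m.T)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_floyd_warshall_oracle(self, seed):
        g, G = random_connected_graph(20, 0.2, seed=seed)
        ours = shortest_path_matrix(g, "hop").matrix
        oracle = nx.floyd_warshall_numpy(G, nodelist=range(20))
        assert np.allclose(ours, oracle)

    def test_weighted_matches_networkx_dijkstra(self):
        g, G = random_connected_graph(12, 0.3, seed=7)
        rng = np.random.default_rng(0)
        lengths = rng.uniform(0.1, 2.0, size=g.n_edges)
        g = SpatialGraph(n_nodes=12, edges=g.edges, lengths=lengths)
        for (u, v), w in zip(g.edges, lengths):
            G[int(u)][int(v)]["weight"] = w
        ours = shortest_path_matrix(g, "weighted").matrix
        oracle = nx.floyd_warshall_numpy(G, nodelist=range(12), weight="weight")
        assert np.allclose(ours, oracle)

    def test_disconnected_reports_component_count(self):
        g = SpatialGraph.from_edges(4, [[0, 1], [2, 3]])
        with pytest.raises(ValueError, match="2 components"):
            shortest_path_matrix(g, "hop")

    def test_weighted_without_lengths_errors(self, path5):
        with pytest.raises(ValueError, match="lengths"):
            shortest_path_matrix(path5, "weighted")

    def test_triangle_inequality_on_random_graphs(self):
        g, _ = random_connected_graph(15, 0.25, seed=11)
        m = shortest_path_matrix(g, "hop").matrix
        n = g.n_nodes
        for k in range(n):
            assert np.all(m <= m[:, [k]] + m[[k], :] + 1e-9)


class TestBfsBall:
    def test_cycle_ball(self, cycle10):
        assert bfs_ball(cycle10, 0, 2).size == 5

    def test_star_center_depth_one(self):
        star = SpatialGraph.from_edges(6, [[0, i] for i in range(1, 6)])
        assert bfs_ball(star, 0, 1).size == 6

    def test_saturation_at_eccentricity(self, path5):
        assert bfs_ball(path5, 0, 4).size == 5
        assert bfs_ball(path5, 0, 99).size == 5

    def test_negative_depth_errors(self, path5):
        with pytest.raises(ValueError):
            bfs_ball(path5, 0, -1)

    @given(depth=st.integers(min_value=0, max_value=6), seed=st.integers(0, 20))
    def test_balls_are_nested(self, depth, seed):
        g, _ = random_connected_graph(12, 0.25, seed=seed)
        inner = set(bfs_ball(g, 0, depth).tolist())
        outer = set(bfs_ball(g, 0, depth + 1).tolist())
        assert inner <= outer


class TestBallGrowth:
    def test_cycle_closed_form(self):
        n = 1000
        g = SpatialGraph.from_edges(n, [[i, (i + 1) % n] for i in range(n)])
        curve = ball_growth(g, 0, 100)
        assert np.array_equal(curve.counts, 2 * curve.depths + 1)

    def test_square_lattice_von_neumann_ball(self):
        side = 21
        g = grid_graph(side)
        center = (side // 2) * side + side // 2
        curve = ball_growth(g, center, 10)
        r = curve.depths
        assert np.array_equal(curve.counts, 2 * r**2 + 2 * r + 1)

    def test_counts_include_origin(self, path5):
        assert ball_growth(path5, 2, 1).counts[0] == 3  # degree 2 + origin

    def test_nondecreasing(self):
        g, _ = random_connected_graph(20, 0.15, seed=3)
        curve = ball_growth(g, 0, 10)
        assert np.all(np.diff(curve.counts) >= 0)


class TestCloseness:
    def test_path_center_hand_sum(self, path5):
        c = closeness_centrality(path5)
        assert c[2] == pytest.approx(1.0 / 6.0)

    def test_complete_graph(self):
        n = 7
        edges = [[i, j] for i in range(n) for j in range(i + 1, n)]
        g = SpatialGraph.from_edges(n, edges)
        assert np.allclose(closeness_centrality(g), 1.0 / (n - 1))

    def test_ranking_matches_row_sum_oracle(self):
        g, _ = random_connected_graph(30, 0.15, seed=5)
        c = closeness_centrality(g)
        sums = shortest_path_matrix(g, "hop").matrix.sum(axis=1)
        assert np.allclose(c, 1.0 / sums)

    @given(seed=st.integers(0, 30))
    def test_invariant_under_relabeling(self, seed):
        g, G = random_connected_graph(12, 0.3, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(12)
        relabeled = SpatialGraph.from_edges(
            12, [[perm[u], perm[v]] for u, v in g.edges]
        )
        c = closeness_centrality(g)
        c2 = closeness_centrality(relabeled)
        assert np.allclose(c, c2[perm])


class TestOriginSelection:
    @pytest.mark.parametrize(
        "n,expected",
        [(500, 10), (50_000, 100), (5, 5), (2000, 20), (999, 10), (10_000, 100)],
    )
    def test_count_clamping(self, n, expected):
        assert origin_count(n) == expected

    def test_origins_sorted_by_closeness_then_id(self, path5):
        origins = select_central_origins(path5)
        assert origins[0] == 2  # unique most-central node
        assert set(origins.tolist()) == {0, 1, 2, 3, 4}
        c = closeness_centrality(path5)
        assert list(c[origins]) == sorted(c, reverse=True)


class TestSampleSubgraph:
    def test_cap_at_least_n_returns_whole_graph(self, cycle10):
        sub, old = sample_subgraph(cycle10, 0, 50)
        assert sub.n_nodes == 10 and sub.n_edges == 10

    def test_cycle_sample_is_connected_and_big_enough(self):
        n = 100
        g = SpatialGraph.from_edges(n, [[i, (i + 1) % n] for i in range(n)])
        sub, _ = sample_subgraph(g, 0, 10)
        assert sub.n_nodes >= 10
        assert sub.is_connected()

    def test_completes_final_shell(self):
        star = SpatialGraph.from_edges(7, [[0, i] for i in range(1, 7)])
        sub, _ = sample_subgraph(star, 0, 3)  # shell at depth 1 has 6 nodes
        assert sub.n_nodes == 7

    @given(seed=st.integers(0, 20), cap=st.integers(1, 15))
    def test_sample_always_connected(self, seed, cap):
        g, _ = random_connected_graph(15, 0.2, seed=seed)
        sub, _ = sample_subgraph(g, 0, cap)
        assert sub.is_connected()

    def test_induced_edges_match_brute_force(self):
        g, G = random_connected_graph(25, 0.15, seed=9)
        sub, old = sample_subgraph(g, 0, 12)
        kept = set(old.tolist())
        expected = {
            (min(a, b), max(a, b))
            for a, b in G.edges()
            if a in kept and b in kept
        }
        got = {(min(old[u], old[v]), max(old[u], old[v])) for u, v in sub.edges}
        assert got == expected


def test_largest_component_extraction():
    g = SpatialGraph.from_edges(7, [[0, 1], [1, 2], [2, 3], [4, 5]])
    comp, old = largest_component(g)
    assert comp.n_nodes == 4
    assert old.tolist() == [0, 1, 2, 3]
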