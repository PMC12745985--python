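import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netcoherence import SpatialGraph

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_connected_graph(n: int, p: float, seed: int):
    """Random G(n, p) conditioned on connectivity; returns (SpatialGraph, nx.Graph)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(G):
            g = SpatialGraph.from_edges(n, list(G.edges()))
            return g, G
    raise RuntimeError("could not draw a connected graph")


@pytest.fixture
def path5():
    return SpatialGraph.from_edges(5, [[0, 1], [1, 2], [2, 3], [3, 4]])


@pytest.fixture
def cycle10():
    edges = [[i, (i + 1) % 10] for i in range(10)]
    return SpatialGraph.from_edges(10, edges)


def grid_graph(side: int) -> SpatialGraph:
    """side x side square lattice with 4-neighbor connectivity."""
    def nid(i, j):
        return i * side + j

    edges = []
    for i in range(side):
        for j in range(side):
            if i + 1 < side:
                edges.append([nid(i, j), nid(i + 1, j)])
            if j + 1 < side:
                edges.append([nid(i, j), nid(i, j + 1)])
    return SpatialGraph.from_edges(side * side, edges)
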