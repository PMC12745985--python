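"""Core graph container and shortest-path machinery for spatial networks.

A spatial network here is an undirected simple graph whose nodes represent
physically localized entities (e.g., DNA polonies) and whose edges record
proximity events.  Everything downstream — dimension estimation, the spatial
constant, and the Gram-matrix spectral scores — is built on the primitives in
this module: the shortest-path distance matrix (SPDM), BFS balls, closeness
centrality, and BFS-based subgraph sampling.

Graphs are stored as a canonical edge array (each row ``u < v``, rows sorted
lexicographically) plus optional per-edge weights (interaction counts), per-edge
lengths (distances for weighted shortest paths), bipartite part labels and
ground-truth node positions.  Heavy lifting (Dijkstra/BFS, components) is done
by :mod:`scipy.sparse.csgraph` on CSR adjacency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialGraph",
    "ShortestPathMatrix",
    "BallGrowthCurve",
    "shortest_path_matrix",
    "bfs_ball",
    "ball_growth",
    "closeness_centrality",
    "select_central_origins",
    "sample_subgraph",
    "largest_component",
]


def canonical_edges(edges: np.ndarray) -> np.ndarray:
    """Return edges with each pair ordered ``u < v`` and rows lexsorted."""
    edges = np.asarray(edges, dtype=np.int64)
    if edges.size == 0:
        return edges.reshape(0, 2)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise ValueError("edges must be an (E, 2) array")
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    out = np.column_stack([lo, hi])
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected simple graph with optional weights, lengths, parts, positions.

    Parameters
    ----------
    n_nodes
        Number of nodes; ids are contiguous integers ``0..n_nodes-1``.
    edges
        ``(E, 2)`` integer array, canonical form (``u < v``, lexsorted).
    weights
        Optional ``(E,)`` positive reals — interaction counts ``w_ij``.
    lengths
        Optional ``(E,)`` positive reals — per-edge distances used by
        weighted shortest paths (typically from the weight→distance
        transform of the polony diffusion model).
    part_labels
        Optional ``(n_nodes,)`` array of 0/1 for bipartite graphs; every
        edge must join different parts.
    positions
        Optional ``(n_nodes, D)`` ground-truth coordinates.
    node_names
        Optional list of external string ids, preserved through I/O.
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray | None = None
    lengths: np.ndarray | None = None
    part_labels: np.ndarray | None = None
    positions: np.ndarray | None = None
    node_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", e)
        if e.size:
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.any(e[:, 0] > e[:, 1]):
                raise ValueError("edges must be canonical (u < v); use from_edges")
            # duplicate rows: canonical + lexsorted makes them adjacent
            if e.shape[0] > 1 and np.any(np.all(np.diff(e, axis=0) == 0, axis=1)):
                raise ValueError("duplicate edges are not allowed")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (e.shape[0],):
                raise ValueError("weights must align with edges")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            object.__setattr__(self, "weights", w)
        if self.lengths is not None:
            d = np.asarray(self.lengths, dtype=float)
            if d.shape != (e.shape[0],):
                raise ValueError("lengths must align with edges")
            if np.any(d <= 0):
                raise ValueError("edge lengths must be positive")
            object.__setattr__(self, "lengths", d)
        if self.part_labels is not None:
            p = np.asarray(self.part_labels)
            if p.shape != (self.n_nodes,):
                raise ValueError("part_labels must have one entry per node")
            if e.size and np.any(p[e[:, 0]] == p[e[:, 1]]):
                raise ValueError("bipartite graph has an intra-part edge")
            object.__setattr__(self, "part_labels", p)
        if self.positions is not None:
            x = np.asarray(self.positions, dtype=float)
            if x.ndim != 2 or x.shape[0] != self.n_nodes:
                raise ValueError("positions must be (n_nodes, D)")
            object.__setattr__(self, "positions", x)
        if self.node_names is not None and len(self.node_names) != self.n_nodes:
            raise ValueError("node_names must have one entry per node")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges,
        weights=None,
        **kwargs,
    ) -> "SpatialGraph":
        """Build a graph from a raw edge list, canonicalizing pair order.

        Edge weights, if given, follow their edges through the reordering.
        Duplicate pairs are an error here; file readers collapse them first.
        """
        e = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        lo = e.min(axis=1)
        hi = e.max(axis=1)
        e = np.column_stack([lo, hi])
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[order]
        return cls(n_nodes=n_nodes, edges=e, weights=weights, **kwargs)

    # ------------------------------------------------------------------ #
    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def adjacency(self, values: str | None = None) -> sp.csr_matrix:
        """Symmetric CSR adjacency; ``values`` in {None, 'weights', 'lengths'}."""
        if values is None:
            data = np.ones(self.n_edges, dtype=float)
        elif values == "weights":
            if self.weights is None:
                raise ValueError("graph has no weights")
            data = self.weights
        elif values == "lengths":
            if self.lengths is None:
                raise ValueError("graph has no edge lengths")
            data = self.lengths
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown values kind {values!r}")
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return sp.csr_matrix(
            (np.concatenate([data, data]), (i, j)),
            shape=(self.n_nodes, self.n_nodes),
        )

    def adjacency_sets(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for u, v in self.edges:
            nbrs[u].add(int(v))
            nbrs[v].add(int(u))
        return nbrs

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(int(u), int(v)): k for k, (u, v) in enumerate(self.edges)}

    # ------------------------------------------------------------------ #
    def connected_components(self) -> tuple[int, np.ndarray]:
        return csgraph.connected_components(self.adjacency(), directed=False)

    def is_connected(self) -> bool:
        return self.connected_components()[0] == 1

    def subgraph(self, nodes) -> tuple["SpatialGraph", np.ndarray]:
        """Induced subgraph on ``nodes``; returns (graph, old-id array).

        New node ``k`` corresponds to old node ``old_ids[k]`` (ascending).
        """
        old_ids = np.unique(np.asarray(nodes, dtype=np.int64))
        if old_ids.size and (old_ids[0] < 0 or old_ids[-1] >= self.n_nodes):
            raise ValueError("subgraph node out of range")
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[old_ids] = True
        keep = mask[self.edges[:, 0]] & mask[self.edges[:, 1]]
        remap = np.full(self.n_nodes, -1, dtype=np.int64)
        remap[old_ids] = np.arange(old_ids.size)
        new_edges = remap[self.edges[keep]]
        g = SpatialGraph(
            n_nodes=int(old_ids.size),
            edges=new_edges,
            weights=None if self.weights is None else self.weights[keep],
            lengths=None if self.lengths is None else self.lengths[keep],
            part_labels=None if self.part_labels is None else self.part_labels[old_ids],
            positions=None if self.positions is None else self.positions[old_ids],
            node_names=None
            if self.node_names is None
            else tuple(self.node_names[i] for i in old_ids),
        )
        return g, old_ids

    def with_edges(self, edges, weights=None, lengths=None) -> "SpatialGraph":
        """Same node set and annotations, different edge set."""
        return replace(
            self,
            edges=canonical_edges(np.asarray(edges)),
            weights=weights,
            lengths=lengths,
        )


@dataclass(frozen=True)
class ShortestPathMatrix:
    """All-pairs shortest-path distances (the SPDM D')."""

    matrix: np.ndarray
    metric_kind: str  # "hop" or "weighted-length"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("SPDM must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BallGrowthCurve:
    """Cumulative BFS-ball sizes N(r') for depths r' = 1..max_depth.

    Counts include the origin node, so N(1) = degree(origin) + 1.
    """

    origin: int
    depths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=np.int64)
        c = np.asarray(self.counts, dtype=np.int64)
        if d.shape != c.shape:
            raise ValueError("depths and counts must align")
        if np.any(np.diff(c) < 0):
            raise ValueError("ball sizes must be nondecreasing")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "counts", c)


# ---------------------------------------------------------------------- #
def _as_matrix(spdm) -> np.ndarray:
    return spdm.matrix if isinstance(spdm, ShortestPathMatrix) else np.asarray(spdm, float)


def require_connected(graph: SpatialGraph, what: str = "operation") -> None:
    n_comp, _ = graph.connected_components()
    if n_comp != 1:
        raise ValueError(
            f"{what} requires a connected graph; input has {n_comp} components "
            "(restrict to the largest component first)"
        )


def largest_component(graph: SpatialGraph) -> tuple[SpatialGraph, np.ndarray]:
    """Largest connected component as an induced subgraph (+ old ids)."""
    n_comp, labels = graph.connected_components()
    if n_comp == 1:
        return graph, np.arange(graph.n_nodes)
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == sizes.argmax())
    logger.warning(
        "graph has %d components (sizes %s); keeping the largest (%d nodes)",
        n_comp,
        sorted(sizes.tolist(), reverse=True)[:5],
        sizes.max(),
    )
    return graph.subgraph(keep)


def shortest_path_matrix(
    graph: SpatialGraph, distance_mode: str = "hop"
) -> ShortestPathMatrix:
    """All-pairs shortest-path distance matrix.

    ``hop`` mode treats every edge as unit length; ``weighted`` mode runs
    Dijkstra over the per-edge ``lengths`` (attach them first, e.g. via the
    weight→distance transform).
    """
    require_connected(graph, "shortest_path_matrix")
    if distance_mode == "hop":
        mat = csgraph.shortest_path(
            graph.adjacency(), method="D", directed=False, unweighted=True
        )
        kind = "hop"
    elif distance_mode == "weighted":
        if graph.lengths is None:
            raise ValueError(
                "weighted mode requires per-edge lengths; "
                "use weight_to_distance to derive them from weights"
            )
        mat = csgraph.shortest_path(
            graph.adjacency("lengths"), method="D", directed=False
        )
        kind = "weighted-length"
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return ShortestPathMatrix(matrix=mat, metric_kind=kind)


def hop_distances_from(graph: SpatialGraph, origin: int, limit=np.inf) -> np.ndarray:
    """Single-source hop distances (inf beyond ``limit`` or off-component)."""
    if not 0 <= origin < graph.n_nodes:
        raise ValueError("origin not in graph")
    return csgraph.dijkstra(
        graph.adjacency(), directed=False, indices=origin, unweighted=True, limit=limit
    )


def bfs_ball(graph: SpatialGraph, origin: int, depth: int) -> np.ndarray:
    """Nodes within hop distance ``depth`` of ``origin`` (origin included)."""
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    dist = hop_distances_from(graph, origin, limit=depth)
    return np.flatnonzero(dist <= depth)


def ball_growth(graph: SpatialGraph, origin: int, max_depth: int) -> BallGrowthCurve:
    """Cumulative ball sizes N(r') for r' = 1..max_depth from ``origin``."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    dist = hop_distances_from(graph, origin, limit=max_depth)
    finite = dist[np.isfinite(dist)].astype(np.int64)
    by_depth = np.bincount(finite, minlength=max_depth + 1)
    counts = np.cumsum(by_depth)[1 : max_depth + 1]
    return BallGrowthCurve(
        origin=int(origin),
        depths=np.arange(1, max_depth + 1),
        counts=counts,
    )


def closeness_centrality(
    graph: SpatialGraph, spdm: ShortestPathMatrix | np.ndarray | None = None
) -> np.ndarray:
    """Closeness C_i = 1 / sum_j d'_ij over hop distances, per node."""
    if spdm is None:
        spdm = shortest_path_matrix(graph, "hop")
    m = _as_matrix(spdm)
    sums = m.sum(axis=1)
    if np.any(~np.isfinite(sums)):
        raise ValueError("closeness centrality requires a connected graph")
    if graph.n_nodes == 1:
        return np.array([1.0])
    return 1.0 / sums


def origin_count(n_nodes: int, fraction=0.01, hard_min=10, soft_max=100) -> int:
    """Number of BFS origins: top ``fraction`` of nodes clamped to [hard_min, soft_max] and to N."""
    n = math.ceil(fraction * n_nodes)
    n = max(n, hard_min)
    n = min(n, soft_max)
    return min(n, n_nodes)


def select_central_origins(
    graph: SpatialGraph,
    fraction: float = 0.01,
    hard_min: int = 10,
    soft_max: int = 100,
    spdm=None,
) -> np.ndarray:
    """Most-central nodes (descending closeness, ties by ascending id).

    The count follows the top-1% heuristic with a hard minimum of 10 and a
    cap of 100, never exceeding N.  These origins minimize boundary effects
    when measuring BFS-ball scaling.
    """
    c = closeness_centrality(graph, spdm=spdm)
    k = origin_count(graph.n_nodes, fraction, hard_min, soft_max)
    order = np.lexsort((np.arange(graph.n_nodes), -c))
    return order[:k]


def sample_subgraph(
    graph: SpatialGraph, origin: int, node_cap: int
) -> tuple[SpatialGraph, np.ndarray]:
    """BFS-sampled induced subgraph of at least ``node_cap`` nodes.

    BFS shells are accumulated from ``origin`` until the cumulative node
    count reaches ``node_cap``; the final shell is completed, so the result
    may slightly exceed the cap.  Returns the relabeled subgraph and the
    array mapping new ids to original ids.
    """
    if node_cap < 1:
        raise ValueError("node_cap must be >= 1")
    dist = hop_distances_from(graph, origin)
    finite = np.isfinite(dist)
    order = np.sort(dist[finite])
    if order.size <= node_cap:
        chosen_depth = np.inf
    else:
        chosen_depth = order[node_cap - 1]
    nodes = np.flatnonzero(finite & (dist <= chosen_depth))
    return graph.subgraph(nodes)
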