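"""Controlled structural noise: false edges, missing edges, filter evaluation.

False edges (barcode collisions, chimeric products) join nodes that are far
apart in physical space; missing edges model shallow sequencing.  Each
perturbation returns the modified graph together with a record of exactly
which edges were added or removed, so filtering methods can be scored against
known noise labels.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import SpatialGraph, canonical_edges

__all__ = [
    "PerturbationRecord",
    "add_false_edges",
    "remove_edges",
    "evaluate_filter",
]


@dataclass(frozen=True)
class PerturbationRecord:
    """Ground-truth labels of a perturbation (added = false edges)."""

    added_edges: np.ndarray  # (A, 2) canonical
    removed_edges: np.ndarray  # (R, 2) canonical
    n_original_edges: int
    false_ratio: float
    missing_ratio: float

    def to_dict(self) -> dict:
        return {
            "added_edges": [[int(u), int(v)] for u, v in self.added_edges],
            "removed_edges": [[int(u), int(v)] for u, v in self.removed_edges],
            "n_original_edges": self.n_original_edges,
            "false_ratio": float(self.false_ratio),
            "missing_ratio": float(self.missing_ratio),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationRecord":
        return cls(
            added_edges=np.asarray(d["added_edges"], dtype=np.int64).reshape(-1, 2),
            removed_edges=np.asarray(d["removed_edges"], dtype=np.int64).reshape(-1, 2),
            n_original_edges=int(d["n_original_edges"]),
            false_ratio=float(d["false_ratio"]),
            missing_ratio=float(d["missing_ratio"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "PerturbationRecord":
        return cls.from_dict(json.loads(s))


def _resolve_count(ratio_or_count, n_edges: int) -> int:
    if isinstance(ratio_or_count, (int, np.integer)):
        return int(ratio_or_count)
    return int(round(float(ratio_or_count) * n_edges))


def add_false_edges(
    graph: SpatialGraph,
    ratio_or_count,
    seed: int = 0,
    min_length: float | None = None,
    respect_bipartite: bool = True,
) -> tuple[SpatialGraph, PerturbationRecord]:
    """Add uniformly random edges between previously non-adjacent pairs.

    ``ratio_or_count`` is an integer count, or a float ratio of the original
    edge count.  ``min_length`` restricts candidates to pairs at least that
    far apart in ground truth (needs positions) — longer false edges hurt
    coherence more.  Bipartite graphs receive cross-part false edges unless
    ``respect_bipartite`` is disabled (which drops the part labels).
    """
    n_new = _resolve_count(ratio_or_count, graph.n_edges)
    if n_new < 0:
        raise ValueError("cannot add a negative number of edges")
    if min_length is not None and graph.positions is None:
        raise ValueError("min_length requires ground-truth positions")
    rng = np.random.default_rng(seed)
    existing = graph.edge_set()
    n = graph.n_nodes

    bipartite = graph.part_labels is not None and respect_bipartite
    if bipartite:
        parts = (
            np.flatnonzero(graph.part_labels == np.unique(graph.part_labels)[0]),
            np.flatnonzero(graph.part_labels != np.unique(graph.part_labels)[0]),
        )
        max_pairs = parts[0].size * parts[1].size
    else:
        max_pairs = n * (n - 1) // 2
    if n_new > max_pairs - len(existing):
        raise ValueError(
            f"requested {n_new} false edges but only "
            f"{max_pairs - len(existing)} non-adjacent pairs exist"
        )

    added: list[tuple[int, int]] = []
    attempts, max_attempts = 0, max(1000, 1000 * n_new)
    while len(added) < n_new:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not find enough eligible non-adjacent pairs "
                f"(placed {len(added)} of {n_new})"
            )
        if bipartite:
            i = int(parts[0][rng.integers(parts[0].size)])
            j = int(parts[1][rng.integers(parts[1].size)])
        else:
            i, j = (int(x) for x in rng.integers(n, size=2))
            if i == j:
                continue
        e = (min(i, j), max(i, j))
        if e in existing:
            continue
        if min_length is not None:
            if np.linalg.norm(graph.positions[i] - graph.positions[j]) < min_length:
                continue
        existing.add(e)
        added.append(e)

    added_arr = (
        canonical_edges(np.asarray(added, dtype=np.int64))
        if added
        else np.empty((0, 2), dtype=np.int64)
    )
    new_edges = (
        np.vstack([graph.edges, added_arr]) if added_arr.size else graph.edges
    )
    out = SpatialGraph(
        n_nodes=n,
        edges=canonical_edges(new_edges),
        part_labels=graph.part_labels if bipartite or graph.part_labels is None else None,
        positions=graph.positions,
        node_names=graph.node_names,
    )
    record = PerturbationRecord(
        added_edges=added_arr,
        removed_edges=np.empty((0, 2), dtype=np.int64),
        n_original_edges=graph.n_edges,
        false_ratio=n_new / graph.n_edges if graph.n_edges else 0.0,
        missing_ratio=0.0,
    )
    return out, record


def _locally_connected(nbrs: list[set[int]], u: int, v: int) -> bool:
    """BFS from u until v is found (edge (u,v) already removed)."""
    seen = {u}
    queue = deque([u])
    while queue:
        x = queue.popleft()
        for y in nbrs[x]:
            if y == v:
                return True
            if y not in seen:
                seen.add(y)
                queue.append(y)
    return False


def remove_edges(
    graph: SpatialGraph,
    missing_ratio: float,
    seed: int = 0,
    max_attempts: int | None = None,
) -> tuple[SpatialGraph, PerturbationRecord]:
    """Remove a fraction of edges while keeping the graph connected.

    Deletions are rejection-sampled: an edge whose removal would disconnect
    the graph is put back and another is drawn.  Raises if the target ratio
    cannot be reached within ``max_attempts`` (default 100 * |E|), reporting
    the ratio achieved.
    """
    if not 0 <= missing_ratio < 1:
        raise ValueError("missing_ratio must be in [0, 1)")
    target = int(round(missing_ratio * graph.n_edges))
    if target == 0:
        record = PerturbationRecord(
            added_edges=np.empty((0, 2), dtype=np.int64),
            removed_edges=np.empty((0, 2), dtype=np.int64),
            n_original_edges=graph.n_edges,
            false_ratio=0.0,
            missing_ratio=0.0,
        )
        return graph, record
    if max_attempts is None:
        max_attempts = 100 * graph.n_edges
    rng = np.random.default_rng(seed)
    nbrs = graph.adjacency_sets()
    alive = [(int(u), int(v)) for u, v in graph.edges]
    removed: list[tuple[int, int]] = []
    attempts = 0
    while len(removed) < target:
        attempts += 1
        if attempts > max_attempts or not alive:
            achieved = len(removed) / graph.n_edges
            raise ValueError(
                f"could not reach missing ratio {missing_ratio:.3f} without "
                f"disconnecting the graph (achieved {achieved:.3f})"
            )
        k = int(rng.integers(len(alive)))
        u, v = alive[k]
        nbrs[u].discard(v)
        nbrs[v].discard(u)
        if _locally_connected(nbrs, u, v):
            alive[k] = alive[-1]
            alive.pop()
            removed.append((u, v))
        else:
            nbrs[u].add(v)
            nbrs[v].add(u)

    removed_set = set(removed)
    keep = np.array([(int(u), int(v)) not in removed_set for u, v in graph.edges])
    out = SpatialGraph(
        n_nodes=graph.n_nodes,
        edges=graph.edges[keep],
        weights=None if graph.weights is None else graph.weights[keep],
        lengths=None if graph.lengths is None else graph.lengths[keep],
        part_labels=graph.part_labels,
        positions=graph.positions,
        node_names=graph.node_names,
    )
    record = PerturbationRecord(
        added_edges=np.empty((0, 2), dtype=np.int64),
        removed_edges=canonical_edges(np.asarray(removed, dtype=np.int64)),
        n_original_edges=graph.n_edges,
        false_ratio=0.0,
        missing_ratio=target / graph.n_edges,
    )
    return out, record


def evaluate_filter(
    record: PerturbationRecord,
    removed_by_filter,
    graph: SpatialGraph | None = None,
) -> tuple[float, float, float]:
    """Precision/recall/F1 of false-edge identification.

    The positive class is "false edge" (an edge the perturbation added); the
    filter's removals are its positive predictions.  If ``graph`` (the
    perturbed graph) is given, removals outside its edge set are an error.
    """
    removed = canonical_edges(np.asarray(list(removed_by_filter), dtype=np.int64).reshape(-1, 2))
    removed_set = {(int(u), int(v)) for u, v in removed}
    if graph is not None:
        extra = removed_set - graph.edge_set()
        if extra:
            raise ValueError(f"filter removed edges not in the graph: {sorted(extra)[:5]}")
    false_set = {(int(u), int(v)) for u, v in record.added_edges}
    tp = len(removed_set & false_set)
    precision = tp / len(removed_set) if removed_set else 0.0
    recall = tp / len(false_set) if false_set else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1
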