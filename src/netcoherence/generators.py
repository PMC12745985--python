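"""Synthetic spatial networks with known ground truth.

Emulates the structures that arise in sequencing-based microscopy: uniform
point clouds in simple regions, K-nearest-neighbor connectivity (unipartite or
bipartite, K=6 in 2D and K=15 in 3D after the mean Voronoi neighbor count),
diffusion-decay connectivity p_ij = exp(-d_ij^2 / L_diff^2), Swiss-roll
manifolds in three edge regimes, and the polony diffusion weight model
w_ij = W exp(-d_ij^2 / L_diff^2) with its inverse distance transform.

Every generated graph carries its ground-truth coordinates, so downstream
claims (dimension, coherence, filtering quality) are testable without any
external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from .graph import SpatialGraph, canonical_edges

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "sample_points",
    "knn_graph",
    "diffusion_graph",
    "swiss_roll",
    "polony_weights",
    "weight_to_distance",
    "diffusion_length",
    "generate_network",
]

SHAPES = ("disk", "sphere", "square", "cube", "swiss_roll")
MODES = ("unipartite_knn", "bipartite_knn", "diffusion")
SWISS_VARIANTS = ("SR", "ISR", "NSR")

#: Swiss-roll strip height: wide enough that the strip is genuinely 2D,
#: while the radial inter-layer gap (2*pi) stays several edge lengths wide
_SWISS_HEIGHT = 40.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic spatial network.

    ``K`` defaults to 6 for 2D shapes and 15 for 3D shapes when left as
    ``None``.  ``l_diff`` is the characteristic diffusion length (same units
    as the coordinates); ``amplitude`` is the polony reactivity amplitude W.
    ``noise_ratio`` is the false-edge fraction of the NSR Swiss-roll variant.
    """

    n_points: int = 3000
    shape: str = "disk"
    mode: str = "unipartite_knn"
    k: int | None = None
    l_diff: float = 0.1
    amplitude: float = 10.0
    swiss_variant: str = "SR"
    noise_ratio: float = 0.10
    bridge_fraction: float = 0.05
    swiss_height: float = _SWISS_HEIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.swiss_variant not in SWISS_VARIANTS:
            raise ValueError(f"unknown swiss_variant {self.swiss_variant!r}")
        if not 0 <= self.noise_ratio < 1:
            raise ValueError("noise_ratio must be in [0, 1)")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        k = self.effective_k
        if not 1 <= k < self.n_points:
            raise ValueError("need 1 <= K < n_points")
        if self.l_diff <= 0:
            raise ValueError("l_diff must be positive")

    @property
    def physical_dim(self) -> int:
        return 2 if self.shape in ("disk", "square") else 3

    @property
    def effective_k(self) -> int:
        if self.k is not None:
            return self.k
        return 6 if self.physical_dim == 2 else 15


# ---------------------------------------------------------------------- #
# Points
# ---------------------------------------------------------------------- #
def sample_points(config: GeneratorConfig) -> np.ndarray:
    """Uniform points in the configured region (unit-radius disk/sphere,
    unit square/cube, or the Swiss-roll strip)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_points
    if config.shape == "disk":
        r = np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if config.shape == "sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(size=n) ** (1.0 / 3.0)
        return v * r[:, None]
    if config.shape == "square":
        return rng.uniform(size=(n, 2))
    if config.shape == "cube":
        return rng.uniform(size=(n, 3))
    if config.shape == "swiss_roll":
        return _swiss_points(config)[0]
    raise ValueError(f"unknown shape {config.shape!r}")  # pragma: no cover


# ---------------------------------------------------------------------- #
# Connectivity
# ---------------------------------------------------------------------- #
def knn_graph(
    points: np.ndarray,
    k: int,
    bipartite: bool = False,
    part_labels: np.ndarray | None = None,
    seed: int = 0,
) -> SpatialGraph:
    """Union-symmetrized K-nearest-neighbor graph.

    An edge exists when either endpoint lists the other among its K nearest
    candidates, so every node has degree >= K.  In bipartite mode neighbors
    are searched only in the opposite part (labels default to a seeded random
    50/50 split); no intra-part edges are produced.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    pairs: list[tuple[int, int]] = []
    if not bipartite:
        if k >= n:
            raise ValueError("K must be smaller than the number of points")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, idx = nn.kneighbors(x)
        for i in range(n):
            for j in idx[i, 1:]:
                pairs.append((i, int(j)))
        labels = None
    else:
        if part_labels is None:
            rng = np.random.default_rng(seed)
            labels = np.zeros(n, dtype=np.int64)
            labels[rng.permutation(n)[: n // 2]] = 1
        else:
            labels = np.asarray(part_labels, dtype=np.int64)
            if labels.shape != (n,):
                raise ValueError("part_labels must have one entry per point")
        for part in (0, 1):
            own = np.flatnonzero(labels == part)
            other = np.flatnonzero(labels != part)
            if k >= other.size:
                raise ValueError("K must be smaller than the opposite part size")
            nn = NearestNeighbors(n_neighbors=k).fit(x[other])
            _, idx = nn.kneighbors(x[own])
            for a, row in zip(own, idx):
                for b in other[row]:
                    pairs.append((int(a), int(b)))
    edges = np.unique(canonical_edges(np.asarray(pairs, dtype=np.int64)), axis=0)
    return SpatialGraph(
        n_nodes=n, edges=edges, positions=x, part_labels=labels
    )


def diffusion_graph(
    points: np.ndarray, l_diff: float, seed: int = 0
) -> SpatialGraph:
    """Random graph with pair-linking probability exp(-d^2 / L_diff^2).

    Models diffusion-mediated interactions: every pair is linked
    independently with a probability that decays with squared distance over
    the characteristic diffusion length.
    """
    if l_diff <= 0:
        raise ValueError("l_diff must be positive")
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    d = pdist(x)
    p = np.exp(-(d**2) / l_diff**2)
    hit = rng.uniform(size=p.size) < p
    iu, ju = np.triu_indices(n, k=1)
    edges = np.column_stack([iu[hit], ju[hit]])
    return SpatialGraph(n_nodes=n, edges=canonical_edges(edges), positions=x)


def interaction_probability(d, l_diff: float) -> np.ndarray:
    """Diffusion interaction probability exp(-d^2 / L_diff^2)."""
    return np.exp(-np.asarray(d, dtype=float) ** 2 / l_diff**2)


# ---------------------------------------------------------------------- #
# Swiss roll
# ---------------------------------------------------------------------- #
def _swiss_points(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Swiss-roll point cloud; returns (xyz, spiral parameter t).

    The strip is parameterized as (t cos t, h, t sin t) for t in
    [1.5*pi, 4.5*pi] (1.5 windings), sampled uniformly by arclength so the
    density is even along the spiral, with h uniform on [0, swiss_height].
    At the default height and 3000 points the radial inter-layer gap (2*pi)
    is about five times the median KNN edge length, so K=6 proximity edges
    stay on the manifold while adjacent layers remain close enough for
    short bridges.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_points
    t0, t1 = 1.5 * np.pi, 4.5 * np.pi
    # arclength element ~ sqrt(1 + t^2) ~ t for t >> 1
    u = rng.uniform(size=n)
    t = np.sqrt(t0**2 + u * (t1**2 - t0**2))
    h = rng.uniform(0.0, config.swiss_height, size=n)
    xyz = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    return xyz, t


def swiss_roll(config: GeneratorConfig) -> SpatialGraph:
    """Swiss-roll benchmark network in one of three edge regimes.

    * ``SR``  — ambient KNN proximity edges only; with the calibrated layer
      gap these stay on the 2D manifold.
    * ``ISR`` — SR plus one short inter-layer bridge for a fraction of nodes
      (``bridge_fraction``): the ambient-nearest node on another winding,
      i.e. an edge that is short in 3D but long along the manifold.
    * ``NSR`` — SR plus uniformly random node pairs totaling
      ``noise_ratio`` of the SR edge count (false edges).
    """
    xyz, t = _swiss_points(config)
    k = config.k if config.k is not None else 6
    base = knn_graph(xyz, k)
    edges = base.edges
    rng = np.random.default_rng(config.seed + 1)

    if config.swiss_variant == "ISR":
        n_bridge = max(1, round(config.bridge_fraction * config.n_points))
        chosen = rng.choice(config.n_points, size=n_bridge, replace=False)
        existing = base.edge_set()
        extra = []
        for i in chosen:
            # candidates on a different winding of the spiral
            off_layer = np.flatnonzero(np.abs(t - t[i]) > np.pi)
            if off_layer.size == 0:
                continue
            dists = np.linalg.norm(xyz[off_layer] - xyz[i], axis=1)
            j = int(off_layer[dists.argmin()])
            e = (min(i, j), max(i, j))
            if e not in existing:
                extra.append(e)
                existing.add(e)
        if extra:
            edges = np.vstack([edges, np.asarray(extra, dtype=np.int64)])
    elif config.swiss_variant == "NSR":
        n_noise = round(config.noise_ratio * base.n_edges)
        existing = base.edge_set()
        extra = []
        while len(extra) < n_noise:
            i, j = rng.integers(config.n_points, size=2)
            if i == j:
                continue
            e = (int(min(i, j)), int(max(i, j)))
            if e in existing:
                continue
            existing.add(e)
            extra.append(e)
        if extra:
            edges = np.vstack([edges, np.asarray(extra, dtype=np.int64)])

    return SpatialGraph(
        n_nodes=config.n_points, edges=canonical_edges(edges), positions=xyz
    )


# ---------------------------------------------------------------------- #
# Polony diffusion weights
# ---------------------------------------------------------------------- #
def polony_weights(
    graph: SpatialGraph,
    amplitude: float,
    l_diff: float,
    integer_counts: bool = False,
) -> SpatialGraph:
    """Assign edge weights from the polony diffusion model.

    ``w_ij = W * exp(-d_ij^2 / L_diff^2)`` with W the reactivity amplitude.
    With ``integer_counts`` the weights are rounded to integer read counts
    with a floor of 1 (this breaks exact invertibility of the distance
    transform).
    """
    if graph.positions is None:
        raise ValueError("polony_weights requires ground-truth positions")
    if amplitude <= 0 or l_diff <= 0:
        raise ValueError("amplitude and l_diff must be positive")
    d = np.linalg.norm(
        graph.positions[graph.edges[:, 0]] - graph.positions[graph.edges[:, 1]], axis=1
    )
    w = amplitude * np.exp(-(d**2) / l_diff**2)
    if integer_counts:
        w = np.maximum(np.round(w), 1.0)
    return SpatialGraph(
        n_nodes=graph.n_nodes,
        edges=graph.edges,
        weights=w,
        part_labels=graph.part_labels,
        positions=graph.positions,
        node_names=graph.node_names,
    )


def weight_to_distance(
    graph: SpatialGraph,
    amplitude: float | None = None,
    l_diff: float = 1.0,
    zero_clamp: float = 1e-6,
) -> SpatialGraph:
    """Invert the diffusion weight model into per-edge distances.

    ``d_ij = sqrt(-ln(w_ij / W)) * L_diff``; ``amplitude=None`` uses the peak
    observed weight as W (the experimental convention).  A weight equal to W
    maps to distance 0 and is clamped to ``zero_clamp * L_diff`` so Dijkstra
    sees a positive length.  L_diff only rescales distances, leaving their
    ranking unchanged.
    """
    if graph.weights is None:
        raise ValueError("weight_to_distance requires edge weights")
    if l_diff <= 0:
        raise ValueError("l_diff must be positive")
    w = graph.weights
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    big_w = float(w.max()) if amplitude is None else float(amplitude)
    if np.any(w > big_w * (1 + 1e-12)):
        raise ValueError("a weight exceeds the amplitude W")
    ratio = np.minimum(w / big_w, 1.0)
    d = np.sqrt(-np.log(ratio)) * l_diff
    d = np.maximum(d, zero_clamp * l_diff)
    return SpatialGraph(
        n_nodes=graph.n_nodes,
        edges=graph.edges,
        weights=graph.weights,
        lengths=d,
        part_labels=graph.part_labels,
        positions=graph.positions,
        node_names=graph.node_names,
    )


def diffusion_length(diffusion_coefficient: float, time: float) -> float:
    """Characteristic diffusion length L_diff = sqrt(8 D t).

    With D ~ 1e-12 m^2/s (short DNA in ~2% agarose) and t of a few minutes,
    L_diff is on the order of 10 micrometers.
    """
    if diffusion_coefficient <= 0 or time <= 0:
        raise ValueError("diffusion coefficient and time must be positive")
    return math.sqrt(8.0 * diffusion_coefficient * time)


# ---------------------------------------------------------------------- #
# One-stop generation
# ---------------------------------------------------------------------- #
def generate_network(config: GeneratorConfig) -> SpatialGraph:
    """Generate a network per the config (points + connectivity + weights)."""
    if config.shape == "swiss_roll":
        return swiss_roll(config)
    points = sample_points(config)
    if config.mode == "unipartite_knn":
        g = knn_graph(points, config.effective_k)
    elif config.mode == "bipartite_knn":
        g = knn_graph(points, config.effective_k, bipartite=True, seed=config.seed)
    else:
        g = diffusion_graph(points, config.l_diff, seed=config.seed)
    return g
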