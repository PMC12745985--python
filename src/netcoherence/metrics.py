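"""Spatial-coherence metrics: spectral scores, network dimension, spatial constant.

A spatially coherent network is one whose shortest-path distances behave like
geodesic distances of a low-dimensional manifold.  Three topology-only
diagnostics quantify this:

* **Spectral scores** — double-center the squared shortest-path distance
  matrix into a Gram matrix ``G = -1/2 J D'^2 J`` and ask how much of its
  spectrum the first D eigenvalues carry (variance contribution ``C_D``) and
  how sharply the spectrum drops after dimension D (spectral gap
  ``1 - lambda_{D+1}/lambda_D``).  For exact D-dimensional Euclidean
  distances both scores are 1.
* **Network dimension** — the growth exponent of BFS-ball sizes,
  ``N(r') ~ alpha * r'^D``, fitted on a log-log sliding window from the most
  central origins.  It should match the physical dimension.
* **Spatial constant** — the dimensionless ``S = <d'> (<k>/N)^{1/D}``,
  the network analog of the mean-line-segment constant of a Euclidean region
  (0.9/sqrt(pi) for a disk); it should be flat across BFS sampling scales.

False (shortcut) edges inflate the dimension, depress the spectral scores and
tilt the spatial-constant profile; missing edges pull the dimension down.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .graph import (
    BallGrowthCurve,
    ShortestPathMatrix,
    SpatialGraph,
    _as_matrix,
    ball_growth,
    bfs_ball,
    hop_distances_from,
    require_connected,
    sample_subgraph,
    select_central_origins,
    shortest_path_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralScores",
    "DimensionEstimate",
    "SpatialConstantProfile",
    "CoherenceReport",
    "EuclideanReference",
    "gram_from_distances",
    "spectral_scores",
    "estimate_dimension",
    "spatial_constant",
    "spatial_constant_profile",
    "euclidean_spatial_constant",
    "distance_correlation_r2",
    "reconstruct_classical_mds",
    "coherence_report",
]

#: full eigendecomposition below this many nodes; sample a BFS subgraph above
EIG_SIZE_THRESHOLD = 4000
#: BFS sampling cap used when a graph exceeds the eigendecomposition threshold
DEFAULT_NODE_CAP = 3000


# ---------------------------------------------------------------------- #
# Spectral scores
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SpectralScores:
    """Gram-matrix eigenvalue summary for a target embedding dimension D."""

    eigenvalues: np.ndarray  # sorted descending
    target_dim: int
    variance_contribution: float  # C_D in [0, 1]
    spectral_gap: float  # 1 - lambda_{D+1}/lambda_D; NaN when undefined
    gap_defined: bool
    denominator: str = "positive"

    def to_dict(self, max_eigenvalues: int = 50) -> dict:
        ev = self.eigenvalues[:max_eigenvalues]
        return {
            "eigenvalues": [float(x) for x in ev],
            "n_eigenvalues_total": int(self.eigenvalues.size),
            "target_dim": self.target_dim,
            "variance_contribution": float(self.variance_contribution),
            "spectral_gap": None if not self.gap_defined else float(self.spectral_gap),
            "gap_defined": self.gap_defined,
            "denominator": self.denominator,
        }


def gram_from_distances(spdm: ShortestPathMatrix | np.ndarray) -> np.ndarray:
    """Gram matrix from distances via double centering: G = -1/2 J D'^2 J.

    J = I - (1/N) 1 1^T places the centroid of the implied point set at the
    origin.  For an exact Euclidean distance matrix of D-dimensional points
    the result has rank at most D with nonnegative spectrum; shortest-path
    distance matrices are generally non-Euclidean and yield some negative
    eigenvalues.
    """
    d = _as_matrix(spdm)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    d2 = d**2
    # J A J without materializing J: subtract row/col means, add grand mean
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    g = -0.5 * (d2 - row - col + grand)
    return 0.5 * (g + g.T)  # enforce exact symmetry


def spectral_scores(
    gram: np.ndarray, target_dim: int, denominator: str = "positive"
) -> SpectralScores:
    """Variance contribution C_D and spectral gap of a Gram matrix.

    ``C_D = sum_{i<=D} lambda_i / sum_j lambda_j`` where the denominator sums
    the nonnegative eigenvalues by default (``denominator="positive"``) so the
    score stays in [0, 1] for non-Euclidean input; ``denominator="abs"`` sums
    absolute values instead.  The gap is ``1 - lambda_{D+1}/lambda_D``,
    flagged undefined when ``lambda_D <= 0``.
    """
    gram = np.asarray(gram, dtype=float)
    n = gram.shape[0]
    if not 1 <= target_dim < n:
        raise ValueError("target_dim must satisfy 1 <= D < N")
    ev = np.linalg.eigvalsh(gram)[::-1]
    top = ev[:target_dim].sum()
    if denominator == "positive":
        denom = ev[ev > 0].sum()
    elif denominator == "abs":
        denom = np.abs(ev).sum()
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    cd = float(np.clip(top / denom, 0.0, 1.0)) if denom > 0 else 0.0
    lam_d = ev[target_dim - 1]
    lam_next = ev[target_dim]
    if lam_d > 0:
        gap = float(1.0 - lam_next / lam_d)
        defined = True
    else:
        gap = float("nan")
        defined = False
    return SpectralScores(
        eigenvalues=ev,
        target_dim=int(target_dim),
        variance_contribution=cd,
        spectral_gap=gap,
        gap_defined=defined,
        denominator=denominator,
    )


# ---------------------------------------------------------------------- #
# Network dimension
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class DimensionEstimate:
    """Pooled BFS-ball scaling dimension with per-origin detail."""

    per_origin_slopes: np.ndarray
    pooled_dimension: float
    slope_std: float
    fit_r2: float
    window: tuple[int, int]  # (start_depth, end_depth) of the first origin's fit
    per_origin_windows: tuple[tuple[int, int], ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_origin_slopes": [float(s) for s in self.per_origin_slopes],
            "pooled_dimension": float(self.pooled_dimension),
            "slope_std": float(self.slope_std),
            "fit_r2": float(self.fit_r2),
            "window": list(self.window),
        }


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept, R^2.  R^2 = 0 when y has no variance."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy <= 0:
        return slope, intercept, 0.0
    return slope, intercept, (sxy * sxy) / (sxx * syy)


def _best_window(
    log_r: np.ndarray, log_n: np.ndarray, min_window: int = 5, frac: float = 0.5
) -> tuple[float, float, int, int]:
    """Best-R^2 contiguous window fit of log N vs log r'.

    Window length is max(min_window, ceil(frac * n_depths)); ties go to the
    window with the smaller start depth.  Returns (slope, r2, start, end) as
    depth indices into the input arrays.
    """
    n = log_r.size
    w = min(max(min_window, math.ceil(frac * n)), n)
    if w < 2:
        raise ValueError("need at least two depths for a log-log fit")
    best = None
    for s in range(0, n - w + 1):
        slope, _, r2 = _ols_r2(log_r[s : s + w], log_n[s : s + w])
        if best is None or r2 > best[1] + 1e-12:
            best = (slope, r2, s, s + w - 1)
    return best


def estimate_dimension(
    graph: SpatialGraph,
    origins=None,
    max_depth: int | None = None,
    min_window: int = 5,
    window_fraction: float = 0.5,
    saturation_fraction: float = 0.5,
) -> DimensionEstimate:
    """Network dimension from BFS-ball growth N(r') ~ alpha r'^D.

    For each origin (default: the top-closeness set), ball sizes are computed
    for every reachable depth, and log N is regressed on log r' over the
    contiguous sliding window with the highest coefficient of determination.
    The pooled dimension is the arithmetic mean of per-origin slopes.

    Depths where the ball already holds more than ``saturation_fraction`` of
    the nodes are excluded: past that point growth is throttled by the
    graph's boundary, not by the geometry of the space, so the power law
    cannot hold (the same reason the spatial-constant sweep stops at half
    the diameter).
    """
    require_connected(graph, "estimate_dimension")
    if origins is None:
        origins = select_central_origins(graph)
    origins = np.asarray(origins, dtype=np.int64)
    if origins.size == 0:
        raise ValueError("need at least one origin")

    slopes, r2s, windows = [], [], []
    for o in origins:
        dist = hop_distances_from(graph, int(o))
        ecc = int(dist[np.isfinite(dist)].max())
        depth = ecc if max_depth is None else min(ecc, max_depth)
        if depth < 3:
            continue
        curve = ball_growth(graph, int(o), depth)
        counts = curve.counts
        cutoff = saturation_fraction * graph.n_nodes
        usable = int(np.searchsorted(counts, cutoff, side="right"))
        usable = max(usable, 3)  # always keep enough depths to fit
        log_r = np.log(curve.depths[:usable].astype(float))
        log_n = np.log(counts[:usable].astype(float))
        slope, r2, s, e = _best_window(log_r, log_n, min_window, window_fraction)
        slopes.append(slope)
        r2s.append(r2)
        windows.append((int(curve.depths[s]), int(curve.depths[e])))
    if not slopes:
        raise ValueError("no origin had at least 3 usable depths")
    slopes = np.asarray(slopes)
    return DimensionEstimate(
        per_origin_slopes=slopes,
        pooled_dimension=float(slopes.mean()),
        slope_std=float(slopes.std()),
        fit_r2=float(np.mean(r2s)),
        window=windows[0],
        per_origin_windows=tuple(windows),
    )


# ---------------------------------------------------------------------- #
# Spatial constant
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SpatialConstantProfile:
    """Per-depth averages of the spatial constant S = <d'> (<k>/N)^(1/D)."""

    target_dim: int
    depths: np.ndarray
    subgraph_sizes: np.ndarray  # mean N per depth
    mean_shortest_paths: np.ndarray  # mean <d'> per depth
    mean_degrees: np.ndarray  # mean <k> per depth
    constants: np.ndarray  # mean S per depth

    def slope(self) -> float:
        """Least-squares slope of S against depth (flat ~ coherent)."""
        s, _, _ = _ols_r2(self.depths.astype(float), self.constants)
        return s

    def to_dict(self) -> dict:
        return {
            "target_dim": self.target_dim,
            "depths": [int(d) for d in self.depths],
            "subgraph_sizes": [float(x) for x in self.subgraph_sizes],
            "mean_shortest_paths": [float(x) for x in self.mean_shortest_paths],
            "mean_degrees": [float(x) for x in self.mean_degrees],
            "constants": [float(x) for x in self.constants],
        }


def spatial_constant(graph: SpatialGraph, target_dim: int, spdm=None) -> float:
    """Direct evaluation of S = <d'> (<k>/N)^(1/D) on a whole graph."""
    if spdm is None:
        spdm = shortest_path_matrix(graph, "hop")
    m = _as_matrix(spdm)
    n = graph.n_nodes
    if n < 2:
        raise ValueError("spatial constant needs at least two nodes")
    mean_d = m.sum() / (n * (n - 1))
    return float(mean_d * (graph.mean_degree / n) ** (1.0 / target_dim))


def spatial_constant_profile(
    graph: SpatialGraph,
    target_dim: int = 2,
    n_origins: int = 10,
    depths=None,
    seed: int = 0,
    min_subgraph: int = 10,
) -> SpatialConstantProfile:
    """Spatial constant across BFS sampling scales.

    Random origin nodes are fixed once per seed; from each, BFS subgraphs of
    increasing depth (default 2 .. ceil(diameter/2)) are extracted, and
    N, <k>, <d'> (mean over all node pairs of the induced subgraph) and S are
    averaged across origins at each depth.  A flat profile indicates scale-
    consistent, Euclidean-like behavior; a decreasing profile points to
    shortcut (false) edges.
    """
    require_connected(graph, "spatial_constant_profile")
    rng = np.random.default_rng(seed)
    origins = rng.choice(graph.n_nodes, size=min(n_origins, graph.n_nodes), replace=False)
    if depths is None:
        full = shortest_path_matrix(graph, "hop")
        diameter = int(full.matrix.max())
        depths = np.arange(2, max(2, math.ceil(diameter / 2)) + 1)
    depths = np.asarray(depths, dtype=np.int64)

    rows = []
    for depth in depths:
        ns, ds, ks, ss = [], [], [], []
        for o in origins:
            nodes = bfs_ball(graph, int(o), int(depth))
            if nodes.size < min_subgraph:
                logger.warning(
                    "skipping origin %d at depth %d: subgraph has %d < %d nodes",
                    o, depth, nodes.size, min_subgraph,
                )
                continue
            sub, _ = graph.subgraph(nodes)
            sub_spdm = shortest_path_matrix(sub, "hop")
            ns.append(sub.n_nodes)
            ds.append(sub_spdm.matrix.sum() / (sub.n_nodes * (sub.n_nodes - 1)))
            ks.append(sub.mean_degree)
            ss.append(spatial_constant(sub, target_dim, spdm=sub_spdm))
        if ns:
            rows.append((int(depth), np.mean(ns), np.mean(ds), np.mean(ks), np.mean(ss)))
    if not rows:
        raise ValueError("no depth produced a subgraph of the minimum size")
    d, n, md, mk, s = map(np.asarray, zip(*rows))
    return SpatialConstantProfile(
        target_dim=int(target_dim),
        depths=d.astype(np.int64),
        subgraph_sizes=n,
        mean_shortest_paths=md,
        mean_degrees=mk,
        constants=s,
    )


@dataclass(frozen=True)
class EuclideanReference:
    """Euclidean counterpart of the spatial constant, from coordinates."""

    mean_distance: float
    beta: float  # <d> / V^{1/D}; 0.9/sqrt(pi) for a uniform disk


def euclidean_spatial_constant(
    points: np.ndarray,
    target_dim: int,
    volume: float | None = None,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> EuclideanReference:
    """Mean pairwise distance and the dimensionless constant beta.

    ``beta = <d> * (density/N)^{1/D} = <d> / V^{1/D}``.  The region volume is
    the convex hull of the points unless given; for a uniform disk,
    <d> ~ 0.9 r and beta ~ 0.9/sqrt(pi).  Pairs are subsampled beyond
    ``max_pairs``.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    total = n * (n - 1) // 2
    if total <= max_pairs:
        from scipy.spatial.distance import pdist

        mean_d = float(pdist(x).mean())
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        mean_d = float(np.linalg.norm(x[i[keep]] - x[j[keep]], axis=1).mean())
    if volume is None:
        try:
            from scipy.spatial import ConvexHull

            volume = float(ConvexHull(x).volume)
        except Exception:
            logger.warning("convex hull failed (degenerate points); beta undefined")
            return EuclideanReference(mean_distance=mean_d, beta=float("nan"))
    beta = mean_d / volume ** (1.0 / target_dim)
    return EuclideanReference(mean_distance=mean_d, beta=float(beta))


# ---------------------------------------------------------------------- #
# Ground-truth comparison and MDS plumbing
# ---------------------------------------------------------------------- #
def distance_correlation_r2(
    graph: SpatialGraph,
    spdm=None,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> float:
    """R^2 between Euclidean and shortest-path distances over node pairs.

    Requires ground-truth positions; pairs are subsampled (seeded) above
    ``max_pairs``.  High R^2 means network distances faithfully encode
    physical distances.
    """
    if graph.positions is None:
        raise ValueError("distance_correlation_r2 requires ground-truth positions")
    if spdm is None:
        spdm = shortest_path_matrix(graph, "hop")
    m = _as_matrix(spdm)
    n = graph.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    if iu.size > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(iu.size, size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    sp_d = m[iu, ju]
    eu_d = np.linalg.norm(graph.positions[iu] - graph.positions[ju], axis=1)
    if sp_d.std() == 0 or eu_d.std() == 0:
        return 0.0
    r = np.corrcoef(sp_d, eu_d)[0, 1]
    return float(r * r)


def reconstruct_classical_mds(gram: np.ndarray, target_dim: int) -> np.ndarray:
    """Classical-MDS coordinates from a double-centered Gram matrix.

    Top-D eigenvectors scaled by sqrt of eigenvalues (negatives clipped to
    zero with a warning); output is centered at the origin and determined up
    to rotation/reflection.
    """
    gram = np.asarray(gram, dtype=float)
    ev, vec = np.linalg.eigh(gram)
    ev, vec = ev[::-1], vec[:, ::-1]
    top = ev[:target_dim]
    if np.any(top <= 0):
        logger.warning(
            "only %d positive eigenvalues for a %d-dimensional reconstruction; "
            "padding with zeros",
            int((top > 0).sum()),
            target_dim,
        )
    coords = vec[:, :target_dim] * np.sqrt(np.clip(top, 0.0, None))
    return coords - coords.mean(axis=0)


# ---------------------------------------------------------------------- #
# Bundled report
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class CoherenceReport:
    """The three coherence diagnostics plus a graph summary, serializable."""

    spectral: SpectralScores
    dimension: DimensionEstimate
    spatial_profile: SpatialConstantProfile
    n_nodes: int
    n_edges: int
    mean_degree: float
    target_dim: int
    seed: int
    schema_version: int = 1
    extra: dict = field(default_factory=dict)

    def to_dict(self, max_eigenvalues: int = 50) -> dict:
        d = {
            "schema_version": self.schema_version,
            "graph_summary": {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "mean_degree": float(self.mean_degree),
            },
            "target_dim": self.target_dim,
            "seed": self.seed,
            "spectral": self.spectral.to_dict(max_eigenvalues),
            "dimension": self.dimension.to_dict(),
            "spatial_constant": self.spatial_profile.to_dict(),
        }
        d.update(self.extra)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CoherenceReport":
        sp = d["spectral"]
        spectral = SpectralScores(
            eigenvalues=np.asarray(sp["eigenvalues"], dtype=float),
            target_dim=sp["target_dim"],
            variance_contribution=sp["variance_contribution"],
            spectral_gap=float("nan") if sp["spectral_gap"] is None else sp["spectral_gap"],
            gap_defined=sp["gap_defined"],
            denominator=sp.get("denominator", "positive"),
        )
        dim = d["dimension"]
        dimension = DimensionEstimate(
            per_origin_slopes=np.asarray(dim["per_origin_slopes"], dtype=float),
            pooled_dimension=dim["pooled_dimension"],
            slope_std=dim["slope_std"],
            fit_r2=dim["fit_r2"],
            window=tuple(dim["window"]),
        )
        sc = d["spatial_constant"]
        profile = SpatialConstantProfile(
            target_dim=sc["target_dim"],
            depths=np.asarray(sc["depths"], dtype=np.int64),
            subgraph_sizes=np.asarray(sc["subgraph_sizes"], dtype=float),
            mean_shortest_paths=np.asarray(sc["mean_shortest_paths"], dtype=float),
            mean_degrees=np.asarray(sc["mean_degrees"], dtype=float),
            constants=np.asarray(sc["constants"], dtype=float),
        )
        g = d["graph_summary"]
        known = {
            "schema_version", "graph_summary", "target_dim", "seed",
            "spectral", "dimension", "spatial_constant",
        }
        return cls(
            spectral=spectral,
            dimension=dimension,
            spatial_profile=profile,
            n_nodes=g["n_nodes"],
            n_edges=g["n_edges"],
            mean_degree=g["mean_degree"],
            target_dim=d["target_dim"],
            seed=d["seed"],
            schema_version=d.get("schema_version", 1),
            extra={k: v for k, v in d.items() if k not in known},
        )

    @classmethod
    def from_json(cls, s: str) -> "CoherenceReport":
        return cls.from_dict(json.loads(s))


def spectral_scores_of_graph(
    graph: SpatialGraph,
    target_dim: int = 2,
    distance_mode: str = "hop",
    node_cap: int = DEFAULT_NODE_CAP,
    size_threshold: int = EIG_SIZE_THRESHOLD,
    seed: int = 0,
    denominator: str = "positive",
) -> SpectralScores:
    """Spectral scores of a graph's SPDM, BFS-sampling very large graphs.

    Graphs above ``size_threshold`` nodes are reduced to a BFS subgraph of
    about ``node_cap`` nodes from a random (seeded) origin before the full
    eigendecomposition.
    """
    g = graph
    if g.n_nodes > size_threshold:
        rng = np.random.default_rng(seed)
        origin = int(rng.integers(g.n_nodes))
        g, _ = sample_subgraph(g, origin, node_cap)
    spdm = shortest_path_matrix(g, distance_mode)
    return spectral_scores(gram_from_distances(spdm), target_dim, denominator)


def coherence_report(
    graph: SpatialGraph,
    target_dim: int = 2,
    seed: int = 0,
    distance_mode: str = "hop",
    n_profile_origins: int = 10,
    node_cap: int = DEFAULT_NODE_CAP,
) -> CoherenceReport:
    """Run all three coherence diagnostics on a connected graph."""
    require_connected(graph, "coherence_report")
    spectral = spectral_scores_of_graph(
        graph, target_dim, distance_mode, node_cap=node_cap, seed=seed
    )
    dimension = estimate_dimension(graph)
    profile = spatial_constant_profile(
        graph, target_dim, n_origins=n_profile_origins, seed=seed
    )
    return CoherenceReport(
        spectral=spectral,
        dimension=dimension,
        spatial_profile=profile,
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        mean_degree=graph.mean_degree,
        target_dim=int(target_dim),
        seed=int(seed),
    )
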