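# Methods

## Model and assumptions

A spatial network is modeled as an undirected simple graph whose nodes carry
(unknown) positions in a D-dimensional Euclidean region and whose edges join
physically nearby nodes. The central assumption behind every metric here is
that for such a graph the shortest-path distance `d'_ij` is an approximately
affine proxy for the geodesic distance between nodes i and j. All three
coherence diagnostics are consequences of that assumption holding — or
failing:

* **Gram spectrum.** If `d'` were exactly proportional to Euclidean distance
  in D dimensions, the double-centered Gram matrix `G = -1/2 J D'² J` would
  be positive semidefinite with rank D. Hop metrics are never exactly
  Euclidean, so G acquires small negative eigenvalues and a tail of small
  positive ones; shortcut edges move spectral mass into that tail.
* **Ball scaling.** The number of nodes within BFS depth r' of a bulk origin
  grows as `α r'^D`. Origins are taken from the top of the closeness ranking
  (`C_i = 1/Σ_j d'_ij`) because closeness-central nodes are the farthest from
  the boundary, where the power law is cleanest.
* **Spatial constant.** `S = ⟨d'⟩ (⟨k⟩/N)^{1/D}` is scale-free in a coherent
  network for the same reason the Euclidean mean-line-segment constant
  (`⟨d⟩ ≈ 0.9 r` in a disk, i.e. `β = 0.9/√π`) is independent of the region's
  size: the mean degree plays the role of point density.

The space is assumed globally Euclidean (flat). Curved or layered samples —
benchmarked here with the Swiss roll — weaken that assumption: coherence then
measures consistency with the manifold's *geodesics*, and edges that are
short in the ambient space but long along the manifold (inter-layer bridges)
legitimately lower the score.

## Estimator details and numerical choices

**Shortest paths.** CSR adjacency + `scipy.sparse.csgraph` (BFS for hop
metrics, Dijkstra for weighted ones). Disconnected inputs are an error in
strict contexts; the high-level entry points restrict to the largest
component with a logged component-size report, since real edge lists
routinely carry satellite components.

**Dimension fit.** Ball counts include the origin (`N(0)=1`, `N(1)=deg+1`)
so logs are always finite; the fit uses depths r' ≥ 1. Per origin, all
contiguous windows of length `max(5, ceil(0.5·L))` over the L available
depths are scored by OLS R² of `log N` vs `log r'`, and the best window's
slope is that origin's estimate (ties to the earlier window; windows with
zero variance in log N score R² = 0 so saturated plateaus never win). Depths
at which the ball already holds more than half of all nodes are discarded
before fitting: beyond that point growth is throttled by the graph's
boundary rather than by the geometry of the space, and retaining the
saturation shoulder biases the slope (upward for shortcut-dominated
networks, downward for diluted ones). At least three depths are always
retained. The pooled dimension is the arithmetic mean of per-origin slopes
(standard deviation reported); the origin count follows the top-1% closeness
heuristic clamped to [10, 100] and to N.

**Spatial-constant profile.** Ten random origins (seeded, fixed across
depths) × BFS depths from 2 to half the hop diameter. `⟨d'⟩` is the mean
over all node pairs of each induced subgraph, mirroring the mean-line-segment
analogy; subgraphs under 10 nodes are skipped with a warning. The profile's
least-squares slope against depth is the flatness summary (≈0 clean,
negative under false edges).

**Spectral scores.** Full symmetric eigendecomposition up to 4000 nodes;
larger graphs are first reduced to a BFS-sampled subgraph of ~3000 nodes
(sampling completes the final BFS shell, so caps may be slightly exceeded).
Because SPDMs are non-Euclidean, the `C_D` denominator sums the nonnegative
eigenvalues by default, keeping `C_D ∈ [0, 1]`; summing absolute values is
available via `denominator="abs"`. `Δλ` is reported as undefined (NaN +
flag) when `λ_D ≤ 0` rather than silently computed. Classical-MDS
reconstruction clips negative eigenvalues to zero (with a warning) and
centers the output.

**Weight model.** `w = W exp(-d²/L²)` inverted as `d = L √(-ln(w/W))`;
`w = W` maps to zero length and is clamped to `10⁻⁶ L` before Dijkstra so
the metric does not collapse. L only rescales distances (rank correlation 1
across L), so the amplitude W — by default the peak observed weight — is the
operative parameter. Integer read-count rounding is opt-in because it breaks
the exact weight↔distance round trip. The characteristic length follows
`L = √(8 D t)`; with D ≈ 10⁻¹² m²/s (short DNA in ~2% agarose) and minutes
of diffusion, L is of order 10 μm.

**Filtering loop.** Edge confidence is either the raw weight or the number
of *simple* paths of exactly L=3 edges between the edge's endpoints,
excluding the direct edge (walks would be inflated by back-and-forth
traversals; an exhaustive enumeration oracle pins the semantics, and the
closed-form `A³` implementation is tested against it). Ties break by score,
then lexicographic edge id, for bit-reproducible rankings. The retention
fraction τ keeps the top `round(τ·|E|)` edges (round-half-up); the
golden-section search over τ ∈ [0, 1] uses internal points
`x₁ = b - (b-a)/φ`, `x₂ = a + (b-a)/φ`, stopping at interval width 0.01 or
50 iterations. The objective — `C_D` of the filtered graph's largest
component — is step-wise and noisy, violating the unimodality the search
formally assumes, so the full evaluation trace is returned and τ* is the
best *evaluated* point; τ = 1 is always evaluated, making ΔS ≥ 0 by
construction. Failed evaluations (collapsed graphs) score −∞ and the search
continues.

## Synthetic data: what it emulates, and what it does not

Generators produce uniform points in a unit disk/sphere/square/cube with
K-nearest-neighbor connectivity, union-symmetrized (edge if either endpoint
nominates the other), K = 6 in 2D and 15 in 3D after the mean Voronoi
neighbor count. Union symmetrization guarantees minimum degree K and, at
these K, connectivity; it yields ⟨k⟩ ≈ 7.1 rather than exactly 6 in 2D.
Bipartite mode searches neighbors only in the opposite part (seeded 50/50
split by default) and produces no intra-part edges. Diffusion connectivity
links each pair independently with `p = exp(-d²/L²)`. False edges are
uniform over non-adjacent pairs (cross-part for bipartite graphs, since
collision artifacts still join opposite chemistries; a minimum-length
variant supports studying edge-length effects). Missing edges are
rejection-sampled so the graph stays connected, erroring with the achieved
ratio when the target is infeasible.

The Swiss-roll benchmark uses `(t cos t, h, t sin t)` for t ∈ [1.5π, 4.5π]
(1.5 windings, sampled uniformly by arclength) and h uniform on [0, 40].
The height is the one genuinely free choice: it sets the strip's aspect
ratio, and with it both the measured dimension of the clean roll (narrow
ribbons read closer to 1, wide strips closer to 2) and the ambient gap
between windings relative to the typical edge (here ≈ 5×, so K = 6
proximity edges stay on-manifold). Height 40 makes the strip wide enough to
read as a genuine 2D manifold (SR dimension ≈ 1.9) while keeping adjacent
layers close enough for short bridges. The ISR variant adds, for 5% of
nodes, one edge to the ambient-nearest node on a different winding
(|Δt| > π); the NSR variant adds uniformly random pairs totaling 10% of the
proximity edge count.

What the generators do **not** emulate: polony growth kinetics, PCR error
spectra, barcode collision statistics, non-uniform sampling density, or any
specific experimental platform's weight distribution. Passing tests
therefore demonstrate that the metrics respond correctly to *idealized*
spatial structure and to generic shortcut/dilution noise — not that they are
calibrated for any particular instrument.

## Problem sizes and observed behavior

Desk-scale experiments use 3000-node networks (matching the regime where the
estimators' defaults — origin counts, eigendecomposition threshold, window
lengths — are exercised without sampling) and five replicate seeds for
stochastic quantities; trend tests use 800–1000 nodes. At these sizes the
clean 2D KNN network measures `D' = 2.0 ± 0.05` and the noisy Swiss roll
`D' ≈ 2.95`; hop-metric quantization keeps the clean disk's `C_D` near 0.77
rather than 1 (the exact-Euclidean limit `C_D = 1` is recovered to 1e-9 when
real distances are supplied), while the elongated Swiss-roll strip scores
higher (≈ 0.83) because its spectrum is dominated by the long axis.

## Known limitations

* A 60% connectivity-preserving dilution of the union-symmetrized K=6
  network measures `D' ≈ 1.8–2.0`, not ≈ 1: the diluted graph keeps a ~40%
  edge surplus over a spanning tree and remains plane-filling at the fitted
  scales. Mean degrees near the spanning-tree limit (⟨k⟩ → 2, e.g. mutual-KNN
  graphs under heavy dilution) are required before the measured dimension
  collapses toward 1; the qualitative direction (missing edges lower the
  dimension) holds throughout.
* The golden-section search assumes a unimodal objective; on step-wise
  `C_D(τ)` it converges to a good, not provably global, threshold. The
  evaluation trace is exposed for inspection.
* Heavy filtering raises `C_D` while shrinking and thinning the graph
  (dimension drops below 2); `ΔS` alone therefore overstates quality when
  τ* is small — inspect the retained edge count alongside it.
* Closeness centrality is computed exactly (all-pairs BFS), which is the
  dominant cost for very large graphs; apply the BFS sampling cap first.
* All metrics assume the underlying space is flat; on curved manifolds they
  measure geodesic consistency instead, and ambient-proximity edges that
  shortcut the manifold (ISR bridges) legitimately read as incoherence.
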