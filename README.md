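# netcoherence

Topology-only quality control for spatially embedded graphs — in particular
DNA barcode networks produced by sequencing-based microscopy (DNA microscopy,
molecular pixelation and related "imaging by sequencing" methods). In these
experiments, barcoded molecular entities (polonies) link to their physical
neighbors, and the resulting proximity graph is all that survives sequencing:
reconstruction of an image depends entirely on how faithfully the network's
topology encodes the geometry of the sample. `netcoherence` measures that
faithfulness — the network's *spatial coherence* — without any ground-truth
coordinates, and uses it to drive edge denoising.

## The three coherence diagnostics

For a connected undirected graph with shortest-path distance matrix
**D**′ (hop counts, or Dijkstra lengths after a weight→distance transform):

1. **Spectral scores.** Double centering turns squared distances into a Gram
   matrix, `G = -1/2 J D'² J` with `J = I - (1/N) 1 1ᵀ`. For exact
   D-dimensional Euclidean distances, G has rank D. Two scores summarize how
   close the network spectrum comes to that ideal: the variance contribution
   `C_D = Σ_{i≤D} λ_i / Σ_j λ_j` (over the nonnegative spectrum) and the
   spectral gap `Δλ = 1 - λ_{D+1}/λ_D`. Both equal 1 for perfectly Euclidean
   distances.
2. **Network dimension.** BFS-ball sizes from the most central nodes (top
   closeness centrality, `C_i = 1/Σ_j d'_ij`) follow a power law
   `N(r') ∝ r'^{D'}`; the log-log slope over the best-R² sliding window
   estimates the intrinsic dimension, which should match the physical one.
3. **Spatial constant.** `S = ⟨d'⟩ (⟨k⟩/N)^{1/D}` is the network analog of
   the mean-line-segment constant of a Euclidean region (`0.9/√π ≈ 0.508`
   for a disk). Measured across BFS sampling scales, it is flat for coherent
   networks and tilts downward when shortcut edges contaminate the metric.

False edges (barcode collisions, chimeric products) inflate the dimension and
crush the spectral scores; missing edges (shallow sequencing) pull the
dimension down. Because `C_D` is computable with no ground truth, it also
serves as the objective of a denoising loop: rank edges by confidence (raw
interaction weight, or the number of indirect length-3 simple paths between
their endpoints), then golden-section-search the retention fraction
`τ ∈ [0, 1]` that maximizes `C_D` of the filtered graph.

The package ships synthetic generators (uniform points in disk/sphere/
square/cube, unipartite and bipartite KNN graphs, diffusion-decay
connectivity `p_ij = exp(-d_ij²/L²)`, three Swiss-roll regimes, and the
polony diffusion weight model `w_ij = W exp(-d_ij²/L²)`), so every claim is
testable without downloads.

## Worked example

```python
import numpy as np
from netcoherence import (
    GeneratorConfig, generate_network, largest_component, add_false_edges,
    coherence_report, score_by_indirect_paths, optimize_filter,
)

g, _ = largest_component(
    generate_network(GeneratorConfig(n_points=1000, shape="disk", seed=0)))
noisy, record = add_false_edges(g, 0.15, seed=1)

for name, net in [("clean", g), ("noisy", noisy)]:
    rep = coherence_report(net, target_dim=2, seed=0)
    print(f"{name}: D'={rep.dimension.pooled_dimension:.2f} "
          f"C_D={rep.spectral.variance_contribution:.3f} "
          f"gap={rep.spectral.spectral_gap:.3f}")

ranking = score_by_indirect_paths(noisy, 3)
result = optimize_filter(noisy, ranking, target_dim=2, seed=0)
print(f"tau*={result.tau_star:.3f} S0={result.s0:.3f} "
      f"S*={result.s_star:.3f} dS={result.delta_s:.3f}")
```

prints

```
clean: D'=1.95 C_D=0.755 gap=0.928
noisy: D'=2.72 C_D=0.058 gap=0.042
tau*=0.634 S0=0.058 S*=0.953 dS=0.895
```

The clean proximity network reads as two-dimensional with a dominant
two-component spectrum; fifteen percent shortcut edges push the apparent
dimension toward three and collapse the variance contribution. The
coherence-guided filter recovers a high-coherence subgraph (`ΔS ≈ 0.9`),
removing every injected false edge (they rank last by indirect-path support).

The same operations are exposed on the command line:

```bash
netcoherence generate --shape disk --n 3000 --k 6 --seed 7 --out-prefix net
netcoherence measure net.edges.tsv --dim 2 --largest-component --seed 7 --out report.json
netcoherence filter net.edges.tsv --score indirect --L 3 --out-prefix filtered
```

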