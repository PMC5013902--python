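# Methods

## Model and assumptions

The package treats clusters as basins of attraction of modes of an unknown
density f on ℝᴰ (or on a graph).  It assumes that (i) distinct clusters
are separated by regions of relatively low density — the valley between
two genuine clusters is deep compared to the shorter of the two density
peaks; and (ii) the K-nearest-neighbour graph captures local topology,
i.e. K is small enough that Knn distances are meaningful even when the
data lie on a lower-dimensional manifold.  Nothing is assumed about
cluster shape, size, or count.

The density at a data point is first the Knn estimator
f⁰ᵢ ∝ (K−1)/(N·V_D·r_K(xᵢ)ᴰ) and is then refined by the random walk with
restart f^(t+1) = αPᵀf^(t) + (1−α)f⁰ on the directed Knn graph.  The walk
pools density evidence from in-neighbours; its fixed point for α < 1 is
the solution of (I − αPᵀ)f = (1−α)f⁰, and the iteration is an
α-contraction in every norm preserved by Pᵀ, so the residual decays at
least like αᵗ.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K (`n_neighbors`) | round(log₂ N), floor 3 | out-degree of the Knn graph; controls the resolution of the density estimate |
| α (`alpha`) | 0.9 | restart damping; 0 keeps raw Knn densities, values near 1 smooth more but converge more slowly (α = 1 is the pure eigenvector limit and may oscillate; it is returned after `max_iter` with a flag) |
| L (`n_levels`) | 100 | number of even saliency thresholds from 1 to 0 |
| `adjust` | on | valley-height inflation by (1 + fraction of points below the valley) |
| `tol`, `max_iter` | 1e-9, 1000 | refinement stopping rule (max-abs change per sweep) |
| metric | euclidean | also: correlation distance, for expression profiles |

K is the parameter that matters.  Small K under-smooths: the density
estimate is spiky, many modes appear, and — because the refinement widens
the dynamic range of densities — along-manifold valleys can become deep
enough in relative terms to survive the sweep.  Large K over-smooths and
can merge genuine clusters.  For datasets with few, large clusters
(including thin non-convex shapes such as the crescent pair) a larger
neighbourhood, around 2–3·log₂ N, is the appropriate scale; the crescent
demonstration in `scripts/acceptance.py` uses K = 27 = 3·log₂ N for this
reason, while compact mixtures are recovered at the default.

## Numerical choices

- **Log-space densities.**  r_K⁻ᴰ under/overflows for D ≳ 300; log f⁰ is
  assembled from log Γ and log r_K and normalised by log-sum-exp.  The
  density vector is normalised to sum to 1; every downstream quantity
  (saliency, adjustment factor, selection) is invariant to positive
  rescaling of the densities, which the test suite asserts.
- **Duplicate points.**  r_K = 0 is replaced by half the smallest positive
  r_K in the dataset, so duplicates receive the highest finite density
  and no infinities propagate.
- **K = 1.**  The estimator's numerator K−1 degenerates to 0; it is
  clamped to 1 so the estimate degrades to a 1/r_K density instead of
  failing.  The default floor K ≥ 3 avoids the case entirely.
- **Deterministic tie-breaks.**  Distance ties in the Knn search and in
  the parent rule resolve to the smaller node index (stable sorts);
  density ties in every comparison treat the smaller index as denser.
  Identical inputs therefore give bit-identical clusterings.
- **Mode filter.**  Candidate modes with in-degree < ceil(K/2) are
  removed.  A removed candidate has no denser in-neighbour, so it climbs
  via its nearest denser *out*-neighbour instead; if none exists its tree
  is force-merged into its most salient valley-adjacent tree before the
  sweep, and flagged as an outlier (label −1, written as 0 by the CLI) if
  it has no adjacency at all.
- **Sweep bookkeeping.**  Merging two trees takes the maximum of their
  heights; valley node-sets to third trees union, so the merged valley
  height is the maximum of the two; the adjustment factor is recomputed
  from the merged valley height.  Within a level, pairs merge in
  descending current saliency with recomputation after each merge, making
  the result independent of tree enumeration order.  The adjusted
  saliency is clipped at 1.
- **Count selection.**  The frequency tally runs over all L+1 levels,
  including the trivial single-cluster plateau when it occurs; ties
  prefer the smaller (coarser) count.  The adjustment count uses the
  refined densities, consistent with every other post-refinement step.

## Synthetic data

The generators produce the structures the algorithm is designed around:
a grid of 2-D Gaussians with equal weights (compact well-separated
mixture; default spacing 8σ, with 3σ as a hard variant), a tight blob in
a sparse uniform background (density contrast), interleaved crescents
(non-convexity), and a coordinate-free chain graph (graph-only input).
All draw from a single seeded generator and are bit-reproducible.

What they deliberately do not emulate: heavy-tailed or skewed
within-cluster noise, dropout and technical zeros of single-cell counts,
correlated features, batch effects, and cluster-size imbalance.  Passing
the synthetic recovery tests therefore demonstrates the mechanics of the
pipeline — density estimation, refinement, mode seeking, stable
selection — not robustness to the full messiness of real expression or
VAF data, where preprocessing (`--min-cells`, `log₂(x+1)`) and metric
choice matter.

## Problem sizes in the test suite

Tests run the full pipeline at N up to 2¹⁴ (scalability check, 64
mixture components) and repeat stochastic recovery at N = 4096 over 20
seeds; oracle comparisons (dense linear solves, brute-force predicates,
exhaustive matchings) run at N ≤ 200 where the oracle is exact and cheap.

## Known limitations

- On thin, noisy manifolds at the default K, spurious along-arc clusters
  can persist the sweep (see the K discussion above).
- Stability selection can legitimately return a count other than the
  generating one when a sample contains a deep density trench: on
  ~10% of 1000-point two-blob samples a persistent intra-blob basin
  split survives selection.  This is a property of the stability rule on
  finite samples, not of the implementation — the trench's valley and
  saliency recomputed by brute force agree exactly with the sweep's.
- The expected cluster count is assumed unique; when two counts tie in
  persistence the coarser one is reported.
- Approximate Knn search is not wired in; the exact chunked search is
  fast to N ~ 10⁵ but the graph build is the asymptotic bottleneck.
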