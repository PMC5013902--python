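# densitycut

Density-based clustering on K-nearest-neighbour graphs, with automatic
selection of the number of clusters.  Aimed at the clustering problems that
recur in genomics: grouping variant allele frequencies (VAFs) of somatic
mutations into tumour clones, partitioning single-cell RNA expression
profiles into cell populations, and finding communities of cells in mass
cytometry (CyTOF) data — settings with large *N*, sometimes large *D*,
irregular cluster shapes, and no known cluster count.

## Method

Given points x₁,…,x_N ∈ ℝᴰ (or a precomputed directed Knn graph), the
pipeline has four steps:

1. **Density estimation.**  Build the directed Knn graph (each node points
   to its K nearest other points) and estimate the density at each point by
   the K-nearest-neighbour estimator

   f⁰(x) = (K−1) / (N · V_D · r_K(x)ᴰ),

   where V_D is the volume of the D-dimensional unit ball and r_K(x) the
   distance to the K-th neighbour.  Evaluation is in log space so that
   D in the hundreds is safe.

2. **Random-walk refinement.**  Knn densities are order statistics and
   noisy, so they are smoothed by a random walk with restart on the graph,

   f^(t+1) = α Pᵀ f^(t) + (1−α) f⁰,   P = D⁻¹W row-stochastic,

   which converges (for α < 1) to f = (1−α)(I − αPᵀ)⁻¹ f⁰.  A node gains
   density when its in-neighbours are dense: being among the K nearest
   neighbours of many dense points is evidence of density.

3. **Mode seeking.**  A *mode* is a node denser than all of its
   in-neighbours; candidate modes with in-degree below K/2 are discarded as
   outlier artefacts.  Every other node climbs to its nearest
   higher-density in-neighbour, and the resulting forest partitions the
   data into basins of attraction — the initial clusters.

4. **Saliency-sweep merging.**  Adjacent trees T₁, T₂ are separated by a
   *valley* (their mutual boundary nodes); the saliency index
   ν = h_valley / min(h_T₁, h_T₂) ∈ [0, 1] is scale-free.  Optionally the
   valley height is inflated by (1 + fraction of points below it), which
   suppresses spurious splits of high-density clusters.  Sweeping a
   threshold evenly from 1 to 0 and merging every pair above it yields a
   nested hierarchy; the cluster count that persists over the most
   thresholds is selected.

Defaults: K = round(log₂ N), α = 0.9, 100 sweep levels, adjustment on.
Complexity is O(NK + C²) beyond the Knn search itself.

## Worked example

```python
from densitycut import DensityCut
from densitycut.metrics import ari, mmm, nmi
from densitycut.synthetic import gaussian_grid

X, truth = gaussian_grid(components=16, n=4096, sep=8.0, seed=0)
model = DensityCut().fit(X)
print(f"K = {model.graph_.k}, refinement iterations = {model.n_iter_}")
print(f"initial modes: {model.forest_.n_trees}")
print(f"selected clusters: {model.n_clusters_}")
print(f"ARI = {ari(model.labels_, truth):.3f}, "
      f"NMI = {nmi(model.labels_, truth):.3f}, "
      f"MMM = {mmm(model.labels_, truth):.3f}")
```

prints

```
K = 12, refinement iterations = 78
initial modes: 75
selected clusters: 16
ARI = 1.000, NMI = 1.000, MMM = 1.000
```

The 4096 points from a 16-component Gaussian mixture first fragment into
75 basins of attraction; the saliency sweep merges them and the stability
rule recovers exactly the 16 generating components, in perfect agreement
with the generating labels (all three external indices equal 1).

`DensityCut` follows the scikit-learn estimator conventions
(`fit`, `fit_predict`, `labels_`, `n_clusters_`, `get_params`/`set_params`)
and also accepts a `NeighbourGraph` in place of coordinates, in which case
the initial density is uniform and refinement acts as a
personalised-PageRank density on the graph.

## Command line

```sh
densitycut simulate --kind gaussian_grid --components 16 --n 4096 --seed 0 --out-prefix sim
densitycut cluster  --input sim.points.tsv --out-prefix run
densitycut eval     --pred run.labels.tsv --truth sim.truth.tsv
```

`cluster` accepts TSV/CSV/MatrixMarket matrices or an edge-list graph
(`--format graph`), plus single-cell preprocessing flags (`--min-cells`,
`--log2-transform`, `--transpose`).  Labels are written 1-based with 0
reserved for outlier points.

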