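"""The DensityCut estimator: the full pipeline behind one sklearn-style API.

The algorithm proceeds in four steps: (i) estimate densities from a
directed Knn graph; (ii) refine them by a random walk with restart;
(iii) cluster by assigning each point to the basin of attraction of a
density mode via graph-based hill climbing; (iv) merge adjacent clusters
across an even saliency-threshold sweep and keep the most stable cluster
count.  The number of clusters is selected automatically.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from . import density as _density
from . import forest as _forest
from . import hierarchy as _hierarchy
from .graph import NeighbourGraph, build_knn_graph, default_k, transition_matrix

__all__ = ["DensityCut", "cluster_points", "cluster_graph"]


class DensityCut(ClusterMixin, BaseEstimator):
    """Density-based clustering on a K-nearest-neighbour graph.

    Parameters
    ----------
    n_neighbors : int or "auto", default="auto"
        Out-degree K of the Knn graph.  "auto" resolves to round(log2 N)
        with a floor of 3.
    alpha : float, default=0.9
        Restart damping of the density-refining random walk; 0 keeps the
        raw Knn densities, values near 1 weight the graph smoothing more
        heavily (and take longer to converge).
    n_levels : int, default=100
        Number of even saliency-threshold steps between 1 and 0.
    adjust : bool, default=True
        Apply the valley-height adjustment before computing saliencies.
    metric : {"euclidean", "correlation"}, default="euclidean"
    knn_method : {"brute", "tree"}, default="brute"
        Exact brute-force search with deterministic tie-breaks, or
        sklearn's tree-accelerated search.
    tol : float, default=1e-9
        Convergence tolerance (max-abs change) of the random walk.
    max_iter : int, default=1000

    Attributes
    ----------
    labels_ : (N,) int array
        Cluster index per point, 0-based; -1 marks points in isolated
        outlier trees that could not be attached anywhere.
    n_clusters_ : int
        The selected stable cluster count.
    density_init_, density_ : DensityVector
        Initial Knn densities and their random-walk refinement.
    n_iter_ : int
        Random-walk iterations used.
    graph_, forest_, merge_tree_ :
        The underlying Knn graph, hill-climbing forest and merge tree.

    Examples
    --------
    >>> from densitycut.synthetic import gaussian_grid
    >>> X, y = gaussian_grid(components=4, n=400, seed=0)
    >>> model = DensityCut().fit(X)
    >>> model.n_clusters_
    4
    """

    def __init__(
        self,
        n_neighbors="auto",
        alpha: float = 0.9,
        n_levels: int = 100,
        adjust: bool = True,
        metric: str = "euclidean",
        knn_method: str = "brute",
        tol: float = 1e-9,
        max_iter: int = 1000,
    ):
        self.n_neighbors = n_neighbors
        self.alpha = alpha
        self.n_levels = n_levels
        self.adjust = adjust
        self.metric = metric
        self.knn_method = knn_method
        self.tol = tol
        self.max_iter = max_iter

    def _resolve_k(self, n: int) -> int:
        if self.n_neighbors == "auto":
            return default_k(n)
        k = int(self.n_neighbors)
        if not 1 <= k < n:
            raise ValueError(f"n_neighbors must satisfy 1 <= K < N, got {k}")
        return k

    def fit(self, X, y=None):
        """Cluster points (array-like, shape (N, D)) or a NeighbourGraph.

        When fitting a bare graph the coordinates are unknown, so the
        initial density is uniform and the refinement reduces to a
        personalised-PageRank density on the graph.
        """
        if isinstance(X, NeighbourGraph):
            graph = X
            dim = None
            f0 = _density.DensityVector(
                np.full(graph.n_nodes, 1.0 / graph.n_nodes), stage="initial"
            )
        else:
            X = check_array(X, dtype=np.float64)
            if X.shape[0] < 2:
                raise ValueError("need at least 2 points")
            dim = X.shape[1]
            k = self._resolve_k(X.shape[0])
            graph = build_knn_graph(
                X, k=k, metric=self.metric, method=self.knn_method
            )
            f0 = _density.knn_density(graph, dim=dim)

        P = transition_matrix(graph)
        f = _density.refine_density(
            P, f0, alpha=self.alpha, tol=self.tol, max_iter=self.max_iter
        )
        modes, removed = _forest.find_modes(graph, f, k=graph.k)
        forest = _forest.build_forest(graph, f, modes, removed)
        valleys = _hierarchy.compute_valleys(graph, f, forest, adjust=self.adjust)
        heights = _hierarchy.tree_heights(forest, f)
        merge_tree = _hierarchy.sweep_merge(
            valleys,
            heights,
            f,
            forest.labels,
            n_levels=self.n_levels,
            adjust=self.adjust,
            outlier_trees=forest.outlier_trees,
        )

        self.graph_ = graph
        self.density_init_ = f0
        self.density_ = f
        self.n_iter_ = f.iterations_used
        self.forest_ = forest
        self.merge_tree_ = merge_tree
        self.labels_ = merge_tree.final_labels
        self.n_clusters_ = merge_tree.selected_count
        return self


def cluster_points(X, **params) -> np.ndarray:
    """Convenience wrapper: fit DensityCut on points, return labels."""
    return DensityCut(**params).fit(X).labels_


def cluster_graph(graph: NeighbourGraph, **params) -> np.ndarray:
    """Convenience wrapper for graph-only input."""
    return DensityCut(**params).fit(graph).labels_
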