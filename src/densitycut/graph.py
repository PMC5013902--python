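"""Directed K-nearest-neighbour graphs and their transition matrices.

The clustering pipeline operates on a directed, unweighted Knn graph: each
node has exactly K out-neighbours (its K nearest points, self excluded) and
a variable number of in-neighbours.  The asymmetry between in- and
out-neighbourhoods is informative: outliers have few or no in-neighbours,
while points in dense regions are among the K nearest neighbours of many
other points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances_chunked
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighbourGraph",
    "build_knn_graph",
    "transition_matrix",
    "read_edge_list",
    "write_edge_list",
    "default_k",
]

_VALID_METRICS = ("euclidean", "correlation")


def default_k(n: int) -> int:
    """Default neighbourhood size, round(log2 N) with a floor of 3."""
    return max(3, int(round(math.log2(n))))


@dataclass
class NeighbourGraph:
    """A directed Knn graph with fixed out-degree K.

    Attributes
    ----------
    out_neighbours : (N, K) int array
        Per node, its K out-neighbours ordered nearest first.
    out_distances : (N, K) float array
        Matching non-negative distances, non-decreasing within a row.
    """

    out_neighbours: np.ndarray
    out_distances: np.ndarray
    _in_indptr: np.ndarray = field(default=None, repr=False)
    _in_sources: np.ndarray = field(default=None, repr=False)
    _in_distances: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.out_neighbours = np.asarray(self.out_neighbours, dtype=np.int64)
        self.out_distances = np.asarray(self.out_distances, dtype=np.float64)
        if self.out_neighbours.shape != self.out_distances.shape:
            raise ValueError("neighbour and distance arrays must have equal shape")
        if self._in_indptr is None:
            self._build_in_adjacency()

    @property
    def n_nodes(self) -> int:
        return self.out_neighbours.shape[0]

    @property
    def k(self) -> int:
        return self.out_neighbours.shape[1]

    def _build_in_adjacency(self) -> None:
        # CSR-like transpose of the out-adjacency: for node v, the sources
        # u with an edge u -> v, plus the edge distances d(u, v).
        n, k = self.out_neighbours.shape
        src = np.repeat(np.arange(n, dtype=np.int64), k)
        dst = self.out_neighbours.ravel()
        dist = self.out_distances.ravel()
        order = np.argsort(dst, kind="stable")
        self._in_sources = src[order]
        self._in_distances = dist[order]
        self._in_indptr = np.zeros(n + 1, dtype=np.int64)
        counts = np.bincount(dst, minlength=n)
        np.cumsum(counts, out=self._in_indptr[1:])

    def in_neighbours(self, v: int) -> np.ndarray:
        """Nodes u with an edge u -> v."""
        return self._in_sources[self._in_indptr[v] : self._in_indptr[v + 1]]

    def in_edge_distances(self, v: int) -> np.ndarray:
        """Distances d(u, v) matching :meth:`in_neighbours`."""
        return self._in_distances[self._in_indptr[v] : self._in_indptr[v + 1]]

    @property
    def in_degrees(self) -> np.ndarray:
        return np.diff(self._in_indptr)

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        n, k = self.out_neighbours.shape
        if n < 2 or k < 1 or k >= n:
            raise ValueError(f"need 1 <= K < N, got N={n}, K={k}")
        if np.any(self.out_neighbours == np.arange(n)[:, None]):
            raise ValueError("a node lists itself as an out-neighbour")
        if self.out_neighbours.min() < 0 or self.out_neighbours.max() >= n:
            raise ValueError("out-neighbour index out of range")
        if np.any(self.out_distances < 0):
            raise ValueError("negative distance")
        if np.any(np.diff(self.out_distances, axis=1) < 0):
            raise ValueError("out_distances not non-decreasing within a row")
        for v in range(n):
            row = self.out_neighbours[v]
            if len(np.unique(row)) != k:
                raise ValueError(f"node {v} has duplicate out-neighbours")
        # transpose consistency
        for v in range(n):
            for u in self.in_neighbours(v):
                if v not in self.out_neighbours[u]:
                    raise ValueError("in/out adjacency out of sync")


def _knn_brute(points: np.ndarray, k: int, metric: str):
    """Exact Knn by chunked pairwise distances with stable tie-breaks.

    Ties in distance are broken by smaller node index (stable argsort), so
    the graph is deterministic regardless of BLAS threading or input order.
    """
    n = points.shape[0]
    out_nb = np.empty((n, k), dtype=np.int64)
    out_d = np.empty((n, k), dtype=np.float64)
    start = 0
    for chunk in pairwise_distances_chunked(points, metric=metric, working_memory=256):
        rows = chunk.shape[0]
        idx = np.arange(start, start + rows)
        chunk[np.arange(rows), idx] = np.inf  # exclude self
        # partition to the K-th distance, then stable-sort only the
        # candidates at or below it so index tie-breaks stay exact
        kth = np.partition(chunk, k - 1, axis=1)[:, k - 1]
        for r in range(rows):
            cand = np.flatnonzero(chunk[r] <= kth[r])
            order = cand[np.argsort(chunk[r, cand], kind="stable")][:k]
            out_nb[start + r] = order
            out_d[start + r] = chunk[r, order]
        start += rows
    # pairwise "correlation" can return tiny negative values from rounding
    np.clip(out_d, 0.0, None, out=out_d)
    return out_nb, out_d


def _knn_tree(points: np.ndarray, k: int, metric: str):
    """Tree-accelerated exact search (sklearn); tie order not guaranteed."""
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(points)
    dist, nbr = nn.kneighbors(points)
    n = points.shape[0]
    out_nb = np.empty((n, k), dtype=np.int64)
    out_d = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        mask = nbr[i] != i
        # if self not returned (duplicate points), drop the last entry
        keep = np.flatnonzero(mask)[:k]
        if len(keep) < k:
            keep = np.arange(k + 1)[:k]
        out_nb[i] = nbr[i, keep]
        out_d[i] = dist[i, keep]
    return out_nb, out_d


def build_knn_graph(
    points: np.ndarray,
    k: int | None = None,
    metric: str = "euclidean",
    method: str = "brute",
) -> NeighbourGraph:
    """Build the directed Knn graph of a point set.

    Parameters
    ----------
    points : (N, D) array
        Coordinates; rows are observations.
    k : int, optional
        Out-degree.  Defaults to round(log2 N), floored at 3.
    metric : {"euclidean", "correlation"}
        Distance used for the neighbour search.
    method : {"brute", "tree"}
        "brute" is exact with deterministic distance-tie handling (smaller
        index wins) and is the default; "tree" delegates to sklearn's
        kd-tree/ball-tree machinery, exact but without a tie guarantee.

    The point itself is never its own neighbour: the K-th neighbour
    distance r_K used by the density estimator is the distance to the K-th
    nearest *other* point.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n = points.shape[0]
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")
    if k is None:
        k = default_k(n)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= K < N, got K={k}, N={n}")
    if metric not in _VALID_METRICS:
        raise ValueError(f"metric must be one of {_VALID_METRICS}, got {metric!r}")
    if method == "brute":
        out_nb, out_d = _knn_brute(points, k, metric)
    elif method == "tree":
        out_nb, out_d = _knn_tree(points, k, metric)
    else:
        raise ValueError(f"unknown method {method!r}")
    return NeighbourGraph(out_nb, out_d)


def transition_matrix(graph: NeighbourGraph) -> sp.csr_matrix:
    """Row-stochastic transition matrix P = D^{-1} W of the Knn graph.

    Every node has out-degree K, so each row has exactly K entries equal
    to 1/K on the out-neighbour columns.
    """
    n, k = graph.out_neighbours.shape
    data = np.full(n * k, 1.0 / k)
    indptr = np.arange(0, n * k + 1, k, dtype=np.int64)
    return sp.csr_matrix(
        (data, graph.out_neighbours.ravel().copy(), indptr), shape=(n, n)
    )


def read_edge_list(path) -> NeighbourGraph:
    """Read a directed Knn graph from a TSV edge list.

    Columns: source, target, distance (0-based node indices).  Every node
    must have the same out-degree; a ragged graph is a format error.
    """
    rows = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if rows.shape[1] != 3:
        raise ValueError("edge list must have columns source, target, distance")
    src = rows[:, 0].astype(np.int64)
    dst = rows[:, 1].astype(np.int64)
    dist = rows[:, 2]
    n = int(max(src.max(), dst.max())) + 1
    deg = np.bincount(src, minlength=n)
    if deg.min() != deg.max():
        raise ValueError(
            f"ragged out-degrees: node {int(np.argmin(deg))} has {deg.min()} "
            f"edges while node {int(np.argmax(deg))} has {deg.max()}"
        )
    k = int(deg[0])
    out_nb = np.empty((n, k), dtype=np.int64)
    out_d = np.empty((n, k), dtype=np.float64)
    order = np.lexsort((dist, src))
    src, dst, dist = src[order], dst[order], dist[order]
    out_nb[:] = dst.reshape(n, k)
    out_d[:] = dist.reshape(n, k)
    return NeighbourGraph(out_nb, out_d)


def write_edge_list(graph: NeighbourGraph, path) -> None:
    """Write the graph as a source<TAB>target<TAB>distance edge list."""
    n, k = graph.out_neighbours.shape
    src = np.repeat(np.arange(n), k)
    with open(path, "w") as fh:
        for s, t, d in zip(src, graph.out_neighbours.ravel(), graph.out_distances.ravel()):
            fh.write(f"{s}\t{t}\t{d:.17g}\n")
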