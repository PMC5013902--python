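"""Mode detection and graph-based hill climbing.

A mode is a node whose density is the highest among all of its
in-neighbours.  In-neighbours (rather than out-neighbours) are used so that
a small, tightly-knit group of fewer than K points that nobody outside
points into can still surface as its own mode; conversely, candidate modes
with in-degree below K/2 are treated as outlier artefacts and removed.

Every non-mode node climbs to its nearest higher-density in-neighbour; the
resulting parent forest partitions the data into basins of attraction, one
initial cluster per surviving mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityVector
from .graph import NeighbourGraph

__all__ = ["ClusterForest", "find_modes", "build_forest"]

MODE = -1  # parent sentinel for roots


@dataclass
class ClusterForest:
    """Hill-climbing forest: parent pointers, roots and initial labels."""

    parent: np.ndarray  # node index, or MODE for roots
    modes: np.ndarray  # root nodes of regular trees
    labels: np.ndarray  # per node, index into the tree list (0..n_trees-1)
    removed_modes: np.ndarray  # candidate modes dropped by the in-degree filter
    outlier_trees: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # tree ids (label values) rooted at a provisional root that could not be
    # attached anywhere; the hierarchy force-merges them, or flags them.

    @property
    def n_trees(self) -> int:
        return int(self.labels.max()) + 1

    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent == MODE)


def _denser(f: np.ndarray, u: int, v: int) -> bool:
    """Strict density order with index tie-break: u denser than v."""
    return f[u] > f[v] or (f[u] == f[v] and u < v)


def find_modes(graph: NeighbourGraph, f: DensityVector, k: int | None = None):
    """Detect density modes and filter out outlier modes.

    A candidate mode is a node denser than every one of its in-neighbours
    (vacuously true for nodes with no in-neighbours).  Candidates whose
    in-degree is below ceil(K/2) are moved to the removed set.  Density
    ties are broken by node index, smaller index treated as denser, so the
    result does not depend on iteration order.

    Returns ``(modes, removed_modes)`` as sorted index arrays.
    """
    if k is None:
        k = graph.k
    fv = np.asarray(f.values)
    n = graph.n_nodes
    candidates = []
    for v in range(n):
        ins = graph.in_neighbours(v)
        if all(not _denser(fv, int(u), v) for u in ins):
            candidates.append(v)
    # vectorised equivalent of the loop above would hide the tie rule; the
    # explicit scan is O(N K) and not a bottleneck.
    threshold = math.ceil(k / 2)
    indeg = graph.in_degrees
    modes = np.array([v for v in candidates if indeg[v] >= threshold], dtype=np.int64)
    removed = np.array([v for v in candidates if indeg[v] < threshold], dtype=np.int64)
    return modes, removed


def build_forest(
    graph: NeighbourGraph,
    f: DensityVector,
    modes: np.ndarray,
    removed_modes: np.ndarray,
) -> ClusterForest:
    """Assign every node a parent and an initial cluster label.

    The parent of a non-root node v is the in-neighbour u with higher
    density (ties by index) that minimises the edge distance d(u, v).  A
    node with no higher-density in-neighbour that is not a surviving mode
    (a removed candidate) instead attaches to its nearest higher-density
    out-neighbour; if none exists it becomes a provisional root and its
    tree is flagged for force-merging during hierarchy construction.

    Density increases strictly along every parent chain (under the
    tie-broken order), which guarantees acyclicity.
    """
    fv = np.asarray(f.values)
    n = graph.n_nodes
    modes = np.asarray(modes, dtype=np.int64)
    if modes.size == 0:
        # no candidate survived the filter: fall back to the densest node
        order = np.lexsort((np.arange(n), -fv))
        modes = np.array([order[0]], dtype=np.int64)
        removed_modes = np.setdiff1d(removed_modes, modes)
        warnings.warn(
            "no mode survived the in-degree filter; using the highest-density "
            "node as the sole mode",
            stacklevel=2,
        )
    mode_set = set(int(m) for m in modes)

    parent = np.full(n, MODE, dtype=np.int64)
    provisional: list[int] = []
    for v in range(n):
        if v in mode_set:
            continue
        best_u, best_d = -1, np.inf
        ins = graph.in_neighbours(v)
        dists = graph.in_edge_distances(v)
        for u, d in zip(ins, dists):
            u = int(u)
            if _denser(fv, u, v) and (
                d < best_d or (d == best_d and (best_u == -1 or u < best_u))
            ):
                best_u, best_d = u, d
        if best_u == -1:
            # removed candidate mode (or isolated node): climb via an
            # out-neighbour instead
            for u, d in zip(graph.out_neighbours[v], graph.out_distances[v]):
                u = int(u)
                if _denser(fv, u, v) and (
                    d < best_d or (d == best_d and (best_u == -1 or u < best_u))
                ):
                    best_u, best_d = u, d
        if best_u == -1:
            provisional.append(v)
        else:
            parent[v] = best_u

    # label each node by its root, iterating nodes from dense to sparse so
    # each parent is labelled before its children
    roots = np.flatnonzero(parent == MODE)
    root_rank = {int(r): i for i, r in enumerate(sorted(roots, key=lambda r: (-fv[r], r)))}
    labels = np.full(n, -1, dtype=np.int64)
    order = np.lexsort((np.arange(n), -fv))
    for v in order:
        v = int(v)
        if parent[v] == MODE:
            labels[v] = root_rank[v]
        else:
            labels[v] = labels[parent[v]]
    if np.any(labels < 0):  # pragma: no cover - guarded by the strict order
        raise AssertionError("parent chains failed to terminate at a root")

    outlier_trees = np.array(
        sorted(root_rank[v] for v in provisional), dtype=np.int64
    )
    return ClusterForest(
        parent=parent,
        modes=np.sort(modes),
        labels=labels,
        removed_modes=np.sort(np.asarray(removed_modes, dtype=np.int64)),
        outlier_trees=outlier_trees,
    )
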