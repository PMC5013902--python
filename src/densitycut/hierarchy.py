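"""Saliency-indexed cluster merging and stability-based model selection.

Adjacent trees of the hill-climbing forest are separated by a *valley*: the
boundary nodes of each tree that have a higher-density in-neighbour in the
other tree.  The valley height is the maximum density over these boundary
nodes, and the saliency index of the pair is the valley height divided by
the height (root density) of the shorter tree — a scale-free number in
[0, 1].  Sweeping a saliency threshold evenly from 1 down to 0 and merging
every pair above the threshold produces a nested hierarchy; the cluster
count that persists over the longest stretch of thresholds is selected as
the most stable clustering.

An optional valley-height adjustment inflates each valley by the fraction
of points whose density lies below it, smoothing spurious splits of
high-density clusters at the cost of slightly earlier merges everywhere.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .density import DensityVector
from .forest import ClusterForest, _denser
from .graph import NeighbourGraph

__all__ = [
    "ValleyRecord",
    "MergeTree",
    "compute_valleys",
    "adjust_valley",
    "saliency",
    "sweep_merge",
    "tree_heights",
]


@dataclass
class ValleyRecord:
    """Boundary structure between two adjacent trees."""

    tree_a: int
    tree_b: int
    valley_nodes: frozenset
    h_valley: float
    h_adjusted: float


@dataclass
class MergeTree:
    """Result of the saliency threshold sweep."""

    levels: np.ndarray  # thresholds 1 -> 0, L+1 values
    merges: list  # (threshold, tree_a, tree_b, saliency)
    counts_per_level: np.ndarray
    frequency: dict  # cluster count -> number of levels
    selected_count: int
    final_labels: np.ndarray  # per node; -1 marks isolated outlier trees
    tree_labels: np.ndarray = field(default=None)  # per initial tree

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def tree_heights(forest: ClusterForest, f: DensityVector) -> np.ndarray:
    """Height of each tree: the density of its root (its maximum)."""
    fv = np.asarray(f.values)
    heights = np.zeros(forest.n_trees)
    for r in forest.roots():
        heights[forest.labels[r]] = fv[r]
    return heights


def compute_valleys(
    graph: NeighbourGraph, f: DensityVector, forest: ClusterForest,
    adjust: bool = True,
) -> list[ValleyRecord]:
    """Find the valley separating every pair of adjacent trees.

    A node v in tree T1 is a boundary point towards T2 if some in-neighbour
    u of v lies in T2 with higher density (density ties broken by node
    index, as everywhere else).  The valley of a pair is the union of the
    two boundary sets; pairs whose valley is empty are not adjacent and
    never merge.
    """
    fv = np.asarray(f.values)
    labels = forest.labels
    valley_sets: dict[tuple[int, int], set] = {}
    n, k = graph.out_neighbours.shape
    for u in range(n):
        lu = labels[u]
        for v in graph.out_neighbours[u]:
            v = int(v)
            lv = labels[v]
            if lu == lv:
                continue
            # edge u -> v: u is an in-neighbour of v
            if _denser(fv, u, v):
                key = (min(lu, lv), max(lu, lv))
                valley_sets.setdefault(key, set()).add(v)
    records = []
    for (a, b), nodes in sorted(valley_sets.items()):
        h = float(max(fv[i] for i in nodes))
        records.append(
            ValleyRecord(
                tree_a=a,
                tree_b=b,
                valley_nodes=frozenset(nodes),
                h_valley=h,
                h_adjusted=adjust_valley(h, f) if adjust else h,
            )
        )
    return records


def adjust_valley(h_valley: float, f: DensityVector) -> float:
    """Inflate a valley height by the fraction of lower-density points.

    Returns ``(1 + |{i : f_i < h}| / N) * h``; the factor lies in [1, 2].
    """
    fv = np.asarray(f.values)
    frac = np.count_nonzero(fv < h_valley) / len(fv)
    return (1.0 + frac) * h_valley


def saliency(h_valley: float, h_ta: float, h_tb: float) -> float:
    """Relative valley height nu = h / min(h_Ta, h_Tb), clipped to [0, 1].

    Scale-free: multiplying all densities by a positive constant leaves it
    unchanged.  The adjusted valley height can exceed the shorter tree, in
    which case the index is clipped at 1.
    """
    shorter = min(h_ta, h_tb)
    if shorter <= 0:
        raise ValueError("tree heights must be positive")
    return float(np.clip(h_valley / shorter, 0.0, 1.0))


class _SweepState:
    """Union-find over trees plus valley bookkeeping for the sweep."""

    def __init__(self, valleys, heights, f: DensityVector, adjust: bool):
        self.f = f
        # sorted copy so the adjustment count is a binary search, not a scan
        self._f_sorted = np.sort(np.asarray(f.values))
        self.adjust = adjust
        self.heights = dict(enumerate(np.asarray(heights, dtype=float)))
        self.uf = {t: t for t in self.heights}
        # valley height per active pair; adjustment recomputed on update
        self.h_valley = {
            (v.tree_a, v.tree_b): v.h_valley for v in valleys
        }

    def find(self, t: int) -> int:
        while self.uf[t] != t:
            self.uf[t] = self.uf[self.uf[t]]
            t = self.uf[t]
        return t

    def pair_saliency(self, a: int, b: int) -> float:
        h = self.h_valley[(a, b)]
        if self.adjust:
            below = np.searchsorted(self._f_sorted, h, side="left")
            h = (1.0 + below / len(self._f_sorted)) * h
        return saliency(h, self.heights[a], self.heights[b])

    def neighbours(self, a: int):
        for x, y in sorted(self.h_valley):
            if x == a:
                yield y
            elif y == a:
                yield x

    def best_pair(self):
        """Active pair with maximal saliency; ties to the smaller id pair."""
        best, best_s = None, -1.0
        for a, b in sorted(self.h_valley):
            s = self.pair_saliency(a, b)
            if s > best_s:
                best, best_s = (a, b), s
        return best, best_s

    def merge(self, a: int, b: int) -> int:
        """Merge tree b into tree a (a < b); returns the representative."""
        rep, gone = min(a, b), max(a, b)
        self.uf[gone] = rep
        self.heights[rep] = max(self.heights[a], self.heights[b])
        del self.heights[gone]
        h_old = self.h_valley
        self.h_valley = {}
        for (x, y), h in h_old.items():
            x = rep if x == gone else x
            y = rep if y == gone else y
            if x == y:
                continue
            key = (min(x, y), max(x, y))
            # merged valleys: node-set union, so the height is the max
            self.h_valley[key] = max(h, self.h_valley.get(key, -np.inf))
        return rep

    def n_active(self) -> int:
        return len(self.heights)


def sweep_merge(
    valleys: list[ValleyRecord],
    heights: np.ndarray,
    f: DensityVector,
    forest_labels: np.ndarray,
    n_levels: int = 100,
    adjust: bool = True,
    outlier_trees=(),
) -> MergeTree:
    """Run the even saliency-threshold sweep and select the stable count.

    Thresholds are nu_l = 1 - l/L for l = 0..L.  At each level the pair
    with the highest current saliency is merged while that saliency
    exceeds the threshold; saliencies are recomputed after every merge
    (heights take the max, valley node-sets union, the adjustment is
    re-evaluated on the merged valley).  The cluster count observed at the
    most levels wins; ties go to the smaller count.

    Provisional outlier trees are force-merged into their most salient
    adjacent tree before the sweep; an outlier tree with no adjacency at
    all keeps the label -1 in ``final_labels``.
    """
    if n_levels < 10:
        raise ValueError("need at least 10 sweep levels")
    heights = np.asarray(heights, dtype=float)
    n_trees = len(heights)
    state = _SweepState(valleys, heights, f, adjust)

    merges: list[tuple[float, int, int, float]] = []
    for t in sorted(int(t) for t in outlier_trees):
        rep = state.find(t)
        best, best_s = None, -1.0
        for other in state.neighbours(rep):
            s = state.pair_saliency(*(min(rep, other), max(rep, other)))
            if s > best_s:
                best, best_s = other, s
        if best is not None:
            a, b = min(rep, best), max(rep, best)
            merges.append((np.nan, a, b, best_s))
            state.merge(a, b)
    # an outlier tree whose representative still has no adjacency cannot
    # be attached anywhere: drop it from the sweep and flag its points
    isolated_reps = {
        state.find(int(t))
        for t in outlier_trees
        if not any(True for _ in state.neighbours(state.find(int(t))))
    }
    for r in isolated_reps:
        del state.heights[r]
    isolated_set = {
        t for t in range(n_trees) if state.find(t) in isolated_reps
    }

    levels = 1.0 - np.arange(n_levels + 1) / n_levels
    counts = np.empty(n_levels + 1, dtype=np.int64)
    snapshots: dict[int, dict[int, int]] = {}

    def snapshot_count():
        c = state.n_active()
        if c not in snapshots:
            snapshots[c] = {t: state.find(t) for t in range(n_trees)
                            if t not in isolated_set}
        return c

    for li, nu in enumerate(levels):
        while state.n_active() > 1:
            pair, s = state.best_pair()
            if pair is None or s <= nu:
                break
            merges.append((float(nu), pair[0], pair[1], s))
            state.merge(*pair)
        counts[li] = snapshot_count()

    frequency = dict(Counter(counts.tolist()))
    # most persistent count; ties favour the coarser clustering
    selected = min(
        frequency, key=lambda c: (-frequency[c], c)
    )
    chosen = snapshots[selected]
    reps = sorted(set(chosen.values()))
    rep_to_label = {r: i for i, r in enumerate(reps)}
    tree_labels = np.full(n_trees, -1, dtype=np.int64)
    for t, r in chosen.items():
        tree_labels[t] = rep_to_label[r]
    final = tree_labels[forest_labels]
    return MergeTree(
        levels=levels,
        merges=merges,
        counts_per_level=counts,
        frequency=frequency,
        selected_count=int(selected),
        final_labels=final,
        tree_labels=tree_labels,
    )
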