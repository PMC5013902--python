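import numpy as np
import pytest

from densitycut.density import DensityVector, knn_density, refine_density
from densitycut.forest import build_forest, find_modes
from densitycut.graph import build_knn_graph, transition_matrix
from densitycut.hierarchy import (
    adjust_valley,
    compute_valleys,
    saliency,
    sweep_merge,
    tree_heights,
)

from conftest import random_graph


def pipeline(points, k=None, adjust=True, n_levels=100, scale=1.0):
    """Run the full pipeline, optionally rescaling densities by `scale`."""
    g = build_knn_graph(points, k=k)
    f = refine_density(transition_matrix(g), knn_density(g, dim=points.shape[1]))
    if scale != 1.0:
        # bypass the sum-to-1 invariant on purpose to probe scale freedom
        f = DensityVector.__new__(DensityVector)
        f.values = np.asarray(
            refine_density(
                transition_matrix(g), knn_density(g, dim=points.shape[1])
            ).values
        ) * scale
        f.stage = "refined"
        f.alpha = 0.9
        f.iterations_used = 0
        f.converged = True
    modes, removed = find_modes(g, f)
    forest = build_forest(g, f, modes, removed)
    valleys = compute_valleys(g, f, forest, adjust=adjust)
    heights = tree_heights(forest, f)
    tree = sweep_merge(
        valleys, heights, f, forest.labels, n_levels=n_levels,
        adjust=adjust, outlier_trees=forest.outlier_trees,
    )
    return g, f, forest, valleys, tree


class TestComputeValleys:
    def test_hand_built_two_tree_valley(self, hand_valley):
        graph, f, forest = hand_valley
        records = compute_valleys(graph, f, forest)
        assert len(records) == 1
        rec = records[0]
        assert rec.valley_nodes == frozenset({2, 4})
        assert rec.h_valley == pytest.approx(0.055)
        # one node (f = 0.04) lies below the valley: factor 1 + 1/6
        assert rec.h_adjusted == pytest.approx(0.055 * (1 + 1 / 6))
        heights = tree_heights(forest, f)
        assert heights.tolist() == [0.30, 0.28]
        assert saliency(rec.h_valley, *heights) == pytest.approx(0.055 / 0.28)
        assert saliency(rec.h_adjusted, *heights) == pytest.approx(11 / 48)

    def test_disconnected_trees_have_no_record(self, hand_valley):
        graph, f, forest = hand_valley
        # cut the two cross edges: redirect 2->4 to 2->0 and 5->2 to 5->3
        nb = graph.out_neighbours.copy()
        nb[2] = [1, 0]
        nb[5] = [4, 3]
        from densitycut.graph import NeighbourGraph

        g2 = NeighbourGraph(nb, graph.out_distances)
        assert compute_valleys(g2, f, forest) == []
        heights = tree_heights(forest, f)
        tree = sweep_merge([], heights, f, forest.labels)
        # disconnected trees persist to threshold 0 as separate clusters
        assert tree.counts_per_level.tolist() == [2] * 101
        assert tree.selected_count == 2

    def test_matches_bruteforce_pair_scan(self, rng):
        for _ in range(10):
            g, _ = random_graph(rng, n=25)
            f = DensityVector(rng.dirichlet(np.ones(25)))
            modes, removed = find_modes(g, f)
            forest = build_forest(g, f, modes, removed)
            records = {(r.tree_a, r.tree_b): r for r in
                       compute_valleys(g, f, forest)}
            fv = f.values
            labels = forest.labels
            expected: dict[tuple, set] = {}
            for v in range(25):  # O(N^2) oracle over all (node, in-node)
                for u in range(25):
                    if v in g.out_neighbours[u] and labels[u] != labels[v]:
                        if fv[u] > fv[v] or (fv[u] == fv[v] and u < v):
                            key = tuple(sorted((labels[u], labels[v])))
                            expected.setdefault(key, set()).add(v)
            assert set(records) == set(expected)
            for key, nodes in expected.items():
                assert records[key].valley_nodes == frozenset(nodes)
                assert records[key].h_valley == pytest.approx(
                    max(fv[i] for i in nodes)
                )


class TestAdjustValley:
    def test_boundary_factors(self):
        f = DensityVector(np.array([0.1, 0.2, 0.3, 0.4]))
        assert adjust_valley(0.05, f) == pytest.approx(0.05)  # below all
        assert adjust_valley(0.5, f) == pytest.approx(1.0)  # above all
        assert adjust_valley(0.25, f) == pytest.approx((1 + 2 / 4) * 0.25)

    def test_factor_never_below_one(self, rng):
        f = DensityVector(rng.dirichlet(np.ones(50)))
        for h in rng.uniform(0, f.values.max() * 2, size=20):
            assert adjust_valley(float(h), f) >= h


class TestSaliency:
    def test_equal_to_shorter_tree_gives_one(self):
        assert saliency(0.3, 0.3, 0.5) == 1.0

    def test_clipped_at_one(self):
        assert saliency(0.9, 0.3, 0.5) == 1.0

    def test_scale_invariance(self):
        for c in (0.1, 3.0, 1e6):
            assert saliency(0.06 * c, 0.30 * c, 0.28 * c) == pytest.approx(
                saliency(0.06, 0.30, 0.28)
            )

    def test_requires_positive_heights(self):
        with pytest.raises(ValueError):
            saliency(0.1, 0.0, 0.5)


class TestSweepMerge:
    def test_level_grid(self, hand_valley):
        graph, f, forest = hand_valley
        valleys = compute_valleys(graph, f, forest)
        tree = sweep_merge(valleys, tree_heights(forest, f), f, forest.labels)
        assert len(tree.levels) == 101
        assert tree.levels[0] == 1.0 and tree.levels[-1] == 0.0
        assert np.allclose(np.diff(tree.levels), -0.01)

    def test_hand_valley_merge_levels(self, hand_valley):
        # adjusted saliency 11/48 ~ 0.229: the pair merges at the first
        # threshold strictly below it (0.22), i.e. 78 levels with 2 clusters
        graph, f, forest = hand_valley
        heights = tree_heights(forest, f)
        valleys = compute_valleys(graph, f, forest)
        tree = sweep_merge(valleys, heights, f, forest.labels, adjust=True)
        assert tree.frequency == {2: 78, 1: 23}
        assert tree.selected_count == 2
        assert tree.final_labels.tolist() == [0, 0, 0, 1, 1, 1]
        # unadjusted saliency 11/56 ~ 0.196: merge happens later (0.19)
        tree_u = sweep_merge(valleys, heights, f, forest.labels, adjust=False)
        assert tree_u.frequency == {2: 81, 1: 20}
        merged_at = tree.merges[0][0]
        merged_at_u = tree_u.merges[0][0]
        assert merged_at > merged_at_u

    def test_adjusted_saliency_never_below_unadjusted(self, rng):
        points = rng.normal(size=(150, 2))
        g, f, forest, valleys, _ = pipeline(points)
        heights = tree_heights(forest, f)
        for rec in valleys:
            s_adj = saliency(rec.h_adjusted, heights[rec.tree_a], heights[rec.tree_b])
            s_raw = saliency(rec.h_valley, heights[rec.tree_a], heights[rec.tree_b])
            assert s_adj >= s_raw

    def test_counts_monotone_and_partitions_nested(self, rng):
        for _ in range(5):
            points = rng.normal(size=(200, 2))
            g, f, forest, valleys, tree = pipeline(points)
            counts = tree.counts_per_level
            assert np.all(np.diff(counts) <= 0)
            # nestedness: replay merges; each level's partition coarsens
            # the previous one because only merge events occur
            assert counts[0] <= forest.n_trees
            expected = min(tree.frequency, key=lambda c: (-tree.frequency[c], c))
            assert tree.selected_count == expected

    def test_threshold_zero_merges_connected_components(self, rng):
        # at threshold 0 every valley-connected pair of trees has merged,
        # so the final count equals the number of connected components of
        # the valley-adjacency graph (computed independently here); two
        # far-apart point groups in particular never merge
        import networkx as nx

        a = rng.normal(size=(120, 2))
        b = rng.normal(loc=(80.0, 0.0), size=(120, 2))
        points = np.vstack([a, b])
        g, f, forest, valleys, tree = pipeline(points, k=5)
        active = [t for t in range(forest.n_trees)
                  if tree.tree_labels[t] != -1]
        G = nx.Graph()
        G.add_nodes_from(active)
        G.add_edges_from((v.tree_a, v.tree_b) for v in valleys
                         if v.tree_a in G and v.tree_b in G)
        assert tree.counts_per_level[-1] == nx.number_connected_components(G)
        # no final cluster spans both groups
        truth = np.repeat([0, 1], 120)
        for lab in np.unique(tree.final_labels):
            if lab == -1:
                continue
            members = truth[tree.final_labels == lab]
            assert len(np.unique(members)) == 1

    def test_density_rescaling_leaves_output_unchanged(self, rng):
        points = rng.normal(size=(180, 2))
        _, _, _, _, t1 = pipeline(points, scale=1.0)
        for c in (1e-3, 7.3):
            _, _, _, _, t2 = pipeline(points, scale=c)
            assert t1.counts_per_level.tolist() == t2.counts_per_level.tolist()
            assert t1.selected_count == t2.selected_count
            assert t1.final_labels.tolist() == t2.final_labels.tolist()

    def test_determinism(self, rng):
        points = rng.normal(size=(150, 2))
        _, _, _, _, t1 = pipeline(points)
        _, _, _, _, t2 = pipeline(points)
        assert t1.counts_per_level.tolist() == t2.counts_per_level.tolist()
        assert t1.final_labels.tolist() == t2.final_labels.tolist()
        assert [m[:3] for m in t1.merges] == [m[:3] for m in t2.merges]

    def test_frequency_tie_prefers_smaller_count(self, hand_valley):
        graph, f, forest = hand_valley
        heights = tree_heights(forest, f)
        valleys = compute_valleys(graph, f, forest)
        # with L=150, adjusted saliency 0.25 puts the merge such that the
        # selection logic must compare exact level counts; just assert the
        # documented rule on the computed frequency table
        tree = sweep_merge(valleys, heights, f, forest.labels, n_levels=150)
        best = max(tree.frequency.values())
        tied = [c for c, v in tree.frequency.items() if v == best]
        assert tree.selected_count == min(tied)

    def test_single_tree_trivial(self, rng):
        f = DensityVector(rng.dirichlet(np.ones(10)))
        labels = np.zeros(10, dtype=np.int64)
        tree = sweep_merge([], np.array([f.values.max()]), f, labels)
        assert tree.selected_count == 1
        assert np.all(tree.final_labels == 0)

    def test_too_few_levels_rejected(self, rng):
        f = DensityVector(rng.dirichlet(np.ones(10)))
        with pytest.raises(ValueError, match="levels"):
            sweep_merge([], np.array([1.0]), f, np.zeros(10, dtype=np.int64),
                        n_levels=5)
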