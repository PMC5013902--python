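import numpy as np
import pytest

from densitycut.graph import NeighbourGraph, build_knn_graph


def random_graph(rng, n=None, k=None, dim=2):
    """A Knn graph over random points; the standard small test input."""
    if n is None:
        n = int(rng.integers(10, 40))
    if k is None:
        k = int(rng.integers(1, min(8, n - 1) + 1))
    points = rng.normal(size=(n, dim))
    return build_knn_graph(points, k=k), points


@pytest.fixture
def rng():
    return np.random.default_rng(20160423)


@pytest.fixture
def chain_1d_graph():
    """1-D points {0, 1, 3} with K=1: the smallest asymmetric graph."""
    return build_knn_graph(np.array([[0.0], [1.0], [3.0]]), k=1)


@pytest.fixture
def two_blobs():
    """Two isotropic Gaussian blobs 10 sigma apart, 200 points each."""
    gen = np.random.default_rng(7)
    a = gen.normal(loc=(0.0, 0.0), scale=1.0, size=(200, 2))
    b = gen.normal(loc=(10.0, 0.0), scale=1.0, size=(200, 2))
    labels = np.repeat([0, 1], 200)
    return np.vstack([a, b]), labels


@pytest.fixture
def hand_valley():
    """Hand-built 6-node, 2-tree graph with a two-node valley.

    Trees {0,1,2} and {3,4,5}; cross edges 2->4 and 5->2.  With the
    densities below, node 4 is a boundary point of tree 1 (in-neighbour 2
    is denser) and node 2 of tree 0 (in-neighbour 5 is denser), so the
    valley is {2, 4} with height f[2] = 0.06.
    """
    from densitycut.density import DensityVector
    from densitycut.forest import MODE, ClusterForest

    out_nb = np.array(
        [[1, 2], [0, 2], [1, 4], [4, 5], [3, 2], [4, 2]]
    )
    out_d = np.array(
        [[1.0, 2.0], [1.0, 1.5], [1.5, 2.5], [1.0, 2.0], [1.0, 2.5], [1.0, 3.0]]
    )
    graph = NeighbourGraph(out_nb, out_d)
    f = DensityVector(np.array([0.30, 0.25, 0.055, 0.28, 0.04, 0.075]))
    forest = ClusterForest(
        parent=np.array([MODE, 0, 1, MODE, 3, 3]),
        modes=np.array([0, 3]),
        labels=np.array([0, 0, 0, 1, 1, 1]),
        removed_modes=np.empty(0, dtype=np.int64),
    )
    return graph, f, forest
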