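"""Seeded generators for data with the structure the algorithm assumes.

Three point-set generators and one graph generator:

* :func:`gaussian_grid` — a mixture of isotropic 2-D Gaussians with equal
  weights, centres on a regular square grid.  The scaling studies sample
  from a mixture of 64 such components; the default spacing of 8 sigma
  makes components well separated, and ``sep=3`` is a useful hard variant.
* :func:`toy_background` — one tight Gaussian blob inside a sparse uniform
  square, the classic dense-cluster-in-noise example where the dense core
  and the surrounding sparse points form the two ground-truth groups.
* :func:`crescents` — two interleaved half-moon arcs, a non-convex shape
  benchmark that defeats centroid-based methods.
* :func:`chain_graph` — a Knn graph supplied without coordinates, for the
  graph-only input path.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; identical arguments give bit-identical output.
"""

from __future__ import annotations

import math

import numpy as np

from .graph import NeighbourGraph, build_knn_graph

__all__ = ["gaussian_grid", "toy_background", "crescents", "chain_graph"]


def gaussian_grid(
    components: int = 64,
    n: int = 4096,
    sep: float = 8.0,
    sigma: float = 1.0,
    seed: int | None = None,
):
    """Sample an equal-weight mixture of 2-D Gaussians on a square grid.

    Parameters
    ----------
    components : int
        Number of mixture components; must be a perfect square so the
        centres tile a sqrt(components) x sqrt(components) grid.
    n : int
        Total number of points; each is assigned a component uniformly.
    sep : float
        Grid spacing in units of sigma.
    sigma : float
        Isotropic component standard deviation.

    Returns
    -------
    points : (n, 2) array
    labels : (n,) int array of component memberships
    """
    side = math.isqrt(components)
    if side * side != components:
        raise ValueError("components must be a perfect square")
    rng = np.random.default_rng(seed)
    centres = np.array(
        [(i * sep * sigma, j * sep * sigma) for i in range(side) for j in range(side)]
    )
    labels = rng.integers(0, components, size=n)
    points = centres[labels] + rng.normal(0.0, sigma, size=(n, 2))
    return points, labels


def toy_background(
    n_cluster: int = 140,
    n_background: int = 100,
    sigma: float = 0.05,
    extent: float = 1.0,
    seed: int | None = None,
):
    """A tight 2-D Gaussian inside a sparse uniform square.

    Label 0 marks the background points, label 1 the dense cluster.
    """
    rng = np.random.default_rng(seed)
    background = rng.uniform(0.0, extent, size=(n_background, 2))
    cluster = rng.normal(extent / 2.0, sigma, size=(n_cluster, 2))
    points = np.vstack([background, cluster])
    labels = np.concatenate(
        [np.zeros(n_background, dtype=np.int64), np.ones(n_cluster, dtype=np.int64)]
    )
    return points, labels


def crescents(n: int = 500, noise: float = 0.08, seed: int | None = None):
    """Two interleaved crescent-shaped clusters with Gaussian noise."""
    rng = np.random.default_rng(seed)
    n_upper = n // 2
    n_lower = n - n_upper
    t_up = rng.uniform(0.0, np.pi, size=n_upper)
    t_lo = rng.uniform(0.0, np.pi, size=n_lower)
    upper = np.column_stack([np.cos(t_up), np.sin(t_up)])
    lower = np.column_stack([1.0 - np.cos(t_lo), 0.5 - np.sin(t_lo)])
    points = np.vstack([upper, lower]) + rng.normal(0.0, noise, size=(n, 2))
    labels = np.concatenate(
        [np.zeros(n_upper, dtype=np.int64), np.ones(n_lower, dtype=np.int64)]
    )
    return points, labels


def chain_graph(n: int = 60, k: int = 4, seed: int | None = None) -> NeighbourGraph:
    """A Knn graph without coordinates, from latent 1-D positions.

    Positions are jittered points on a line, so the graph is a noisy chain;
    only the graph is returned, exercising the graph-only input path where
    the initial density must be taken as uniform.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.uniform(0.0, float(n), size=n))[:, None]
    return build_knn_graph(positions, k=k)
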