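"""Knn density estimation and random-walk refinement.

The initial density at a point x is the K-nearest-neighbour estimator

    f_K(x) = (K - 1) / (N * V_D * r_K(x)^D)

where V_D is the volume of the unit ball in D dimensions and r_K(x) the
distance from x to its K-th nearest other point.  Because order statistics
are noisy, the estimate is refined by a random walk with restart on the Knn
graph,

    f^{t+1} = alpha * P^T f^t + (1 - alpha) * f^0,

whose fixed point for alpha < 1 is f = (1 - alpha) (I - alpha P^T)^{-1} f^0.
A node accumulates density from its in-neighbours: a vertex is dense if it
is among the K nearest neighbours of many dense vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp

from .graph import NeighbourGraph

__all__ = ["DensityVector", "knn_density", "refine_density", "log_unit_ball_volume"]


@dataclass
class DensityVector:
    """Per-node densities normalised to sum to one."""

    values: np.ndarray
    stage: str = "initial"  # "initial" or "refined"
    alpha: float = 0.0
    iterations_used: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("densities must be finite and non-negative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("densities must sum to 1")

    def __len__(self) -> int:
        return len(self.values)


def log_unit_ball_volume(dim: int) -> float:
    """log V_D = (D/2) log(pi) - log Gamma(D/2 + 1)."""
    return 0.5 * dim * np.log(np.pi) - gammaln(0.5 * dim + 1.0)


def knn_density(graph: NeighbourGraph, dim: int, normalize: bool = True):
    """Initial Knn density estimate from the K-th neighbour distances.

    Evaluated in log space (log f ~ -D log r_K up to constants) so that it
    survives dimensions in the hundreds, where r_K^D would under- or
    overflow.  Duplicate points (r_K = 0) are given half the smallest
    positive r_K, so they receive the highest finite density.

    Returns a :class:`DensityVector` when ``normalize`` (the default), else
    the raw unnormalised values of the estimator.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rk = graph.out_distances[:, -1].astype(np.float64).copy()
    n, k = graph.out_neighbours.shape
    positive = rk[rk > 0]
    if positive.size == 0:
        raise ValueError("all points are identical: every r_K is zero")
    rk[rk == 0] = positive.min() / 2.0
    log_f = (
        np.log(max(k - 1, 1))
        - np.log(n)
        - log_unit_ball_volume(dim)
        - dim * np.log(rk)
    )
    if not normalize:
        return np.exp(log_f)
    values = np.exp(log_f - logsumexp(log_f))
    values /= values.sum()  # absorb residual rounding
    return DensityVector(values, stage="initial")


def refine_density(
    P: sp.spmatrix,
    f0: DensityVector,
    alpha: float = 0.9,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> DensityVector:
    """Refine densities by a random walk with restart on the Knn graph.

    Iterates f^{t+1} = alpha P^T f^t + (1-alpha) f^0 until the max-abs
    change drops below ``tol`` or ``max_iter`` is reached.  The iteration
    is a contraction with factor alpha, so for alpha < 1 it converges to
    the unique fixed point; alpha = 1 converges to a left eigenvector of P
    and may oscillate, in which case the result after ``max_iter`` sweeps
    is returned with ``converged=False``.

    Each sweep preserves the total mass: sum f^{t+1} =
    alpha * sum f^t + (1-alpha) * sum f^0 = 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    f_init = np.asarray(f0.values, dtype=np.float64)
    if alpha == 0.0:
        return DensityVector(f_init.copy(), stage="refined", alpha=0.0,
                             iterations_used=0, converged=True)
    Pt = P.T.tocsr()
    restart = (1.0 - alpha) * f_init
    f = f_init.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f_next = alpha * (Pt @ f) + restart
        delta = np.max(np.abs(f_next - f))
        f = f_next
        if delta < tol:
            converged = True
            break
    f = np.clip(f, 0.0, None)
    f /= f.sum()
    return DensityVector(
        f, stage="refined", alpha=alpha, iterations_used=iterations,
        converged=converged,
    )


def refine_density_exact(P: sp.spmatrix, f0: DensityVector, alpha: float) -> np.ndarray:
    """Closed-form fixed point (1-alpha)(I - alpha P^T)^{-1} f^0, alpha < 1.

    Dense linear solve; intended as a reference for small graphs.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("closed form requires alpha < 1")
    n = P.shape[0]
    A = np.eye(n) - alpha * P.toarray().T
    return np.linalg.solve(A, (1.0 - alpha) * np.asarray(f0.values))
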