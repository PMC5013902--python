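"""External clustering validation indices.

Maximum-matching measure (MMM), normalized mutual information (NMI),
adjusted Rand index (ARI) and mean silhouette width, all comparing a
predicted partition against a reference partition.  NMI uses the geometric
mean normalisation by default; MMM solves a maximum-weight one-to-one
assignment between predicted clusters and reference classes over the
contingency table.

Points carrying an outlier label in the prediction can be excluded before
computing an index, matching the convention of reporting indices over the
clustered points only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["contingency", "mmm", "nmi", "ari", "silhouette_mean"]


def _drop_outliers(pred, truth, outlier_label):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("label vectors must have equal length")
    if len(pred) == 0:
        raise ValueError("empty labelings")
    if outlier_label is not None:
        keep = pred != outlier_label
        pred, truth = pred[keep], truth[keep]
        if len(pred) == 0:
            raise ValueError("all points are labelled as outliers")
    return pred, truth


def contingency(pred, truth) -> np.ndarray:
    """R x C table of co-occurrence counts, predicted x reference."""
    return contingency_matrix(truth, pred).T


def mmm(pred, truth, outlier_label=None) -> float:
    """Maximum-matching measure in [0, 1].

    The best one-to-one matching of predicted clusters to reference
    classes (Hungarian assignment on the contingency table, rectangular
    tables implicitly zero-padded); the matched mass divided by n.
    """
    pred, truth = _drop_outliers(pred, truth, outlier_label)
    table = contingency(pred, truth)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / table.sum()


def nmi(pred, truth, outlier_label=None, average_method: str = "geometric") -> float:
    """Normalized mutual information, geometric-mean normalisation."""
    pred, truth = _drop_outliers(pred, truth, outlier_label)
    return float(
        normalized_mutual_info_score(truth, pred, average_method=average_method)
    )


def ari(pred, truth, outlier_label=None) -> float:
    """Adjusted Rand index: 1 at identity, expectation 0 under the null."""
    pred, truth = _drop_outliers(pred, truth, outlier_label)
    return float(adjusted_rand_score(truth, pred))


def silhouette_mean(points, labels, outlier_label=None) -> float:
    """Mean silhouette width over all points, Euclidean distances."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if outlier_label is not None:
        keep = labels != outlier_label
        points, labels = points[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for fewer than 2 clusters")
    return float(silhouette_score(points, labels, metric="euclidean"))
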