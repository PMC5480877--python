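"""Correlation-distance hierarchical clustering and silhouette validation.

The TSS feature matrix is z-scaled per feature, pairwise dissimilarity is
``(1 - Pearson r) / 2`` (0 for identical profiles, 1 for anti-correlated,
0.5 for uncorrelated) and agglomeration uses unweighted average linkage.
Cluster quality is judged with the silhouette coefficient
``s = (B - A) / max(A, B)`` where A is a case's mean distance to its own
cluster and B the smallest mean distance to another cluster; averages above
0.5 indicate a reasonable partition, below 0.2 no cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .intervals import ValidationError


def zscale(matrix) -> np.ndarray:
    """Per-column z scaling (sample SD); constant columns map to zeros."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("zscale needs a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValidationError("zscale requires finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = np.zeros_like(X)
    ok = sd > 0
    out[:, ok] = (X[:, ok] - mean[ok]) / sd[ok]
    return out


def corr_distance(x, y) -> float:
    """(1 - Pearson r) / 2 in [0, 1]; zero-variance input -> 0.5 (r := 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("vectors must have equal length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.5
    r = float(np.corrcoef(x, y)[0, 1])
    return min(max((1.0 - r) / 2.0, 0.0), 1.0)


def corr_distance_matrix(X) -> np.ndarray:
    """Pairwise (1 - r)/2 matrix; rows with zero variance get 0.5 off-diagonal."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    n = X.shape[0]
    D = np.full((n, n), 0.5)
    if ok.sum() >= 2:
        R = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = np.clip((1.0 - R) / 2.0, 0.0, 1.0)
    elif ok.sum() == 1:
        i = int(np.flatnonzero(ok)[0])
        D[i, i] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


def silhouette(dist, labels) -> tuple[np.ndarray, float]:
    """Per-object silhouettes and their average from a distance matrix.

    Objects in singleton clusters get s = 0, as does the degenerate
    A = B = 0 case.  A single cluster overall is an error (B undefined).
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise ValidationError("distance matrix and labels disagree")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        A = D[i, own & (np.arange(n) != i)].mean()
        B = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(A, B)
        s[i] = 0.0 if denom == 0 else (B - A) / denom
    return s, float(s.mean())


@dataclass
class ClusterResult:
    """Labels, merge history and silhouettes of one clustering run."""

    labels: pd.Series
    merge_history: list[tuple[int, int, float]]
    per_object_s: pd.Series
    average_sc: float
    linkage_matrix: np.ndarray = field(repr=False, default=None)


class CorrelationClustering(ClusterMixin, BaseEstimator):
    """Average-linkage agglomerative clustering on (1 - r)/2 distance.

    Parameters
    ----------
    n_clusters : int — where to cut the dendrogram (2 for the rod/common
        TSS partition).
    scale : bool — z-scale feature columns first (recommended: raw counts
        would be dominated by the largest-magnitude assay).

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of cluster indices, renumbered so cluster 0 is the
        one containing the lowest row index.
    linkage_ : scipy linkage matrix; merge_history_ its (i, j, height) view.
    silhouette_samples_, silhouette_ : per-object and average silhouette
        on the same distance matrix (only when n_clusters >= 2).
    """

    def __init__(self, n_clusters: int = 2, scale: bool = True) -> None:
        self.n_clusters = n_clusters
        self.scale = scale

    def fit(self, X, y=None) -> "CorrelationClustering":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValidationError(f"n_clusters must be in [1, {n}]")
        Z = zscale(X) if self.scale else X
        D = corr_distance_matrix(Z)
        link = hierarchy.linkage(squareform(D, checks=False), method="average")
        raw = hierarchy.fcluster(link, t=self.n_clusters, criterion="maxclust")
        # renumber deterministically by first occurrence
        order: dict[int, int] = {}
        for lab in raw:
            if lab not in order:
                order[lab] = len(order)
        self.labels_ = np.array([order[lab] for lab in raw])
        self.linkage_ = link
        self.merge_history_ = [
            (int(a), int(b), float(h)) for a, b, h, _ in link
        ]
        self.distances_ = D
        if len(np.unique(self.labels_)) >= 2:
            self.silhouette_samples_, self.silhouette_ = silhouette(D, self.labels_)
        else:
            self.silhouette_samples_, self.silhouette_ = np.zeros(n), 0.0
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def average_linkage(matrix, k: int, index=None, scale: bool = True) -> ClusterResult:
    """Functional wrapper around CorrelationClustering."""
    X = np.asarray(matrix, dtype=float)
    idx = pd.Index(index if index is not None else range(X.shape[0]), name="tss_id")
    model = CorrelationClustering(n_clusters=k, scale=scale).fit(X)
    return ClusterResult(
        labels=pd.Series(model.labels_, index=idx),
        merge_history=model.merge_history_,
        per_object_s=pd.Series(model.silhouette_samples_, index=idx),
        average_sc=model.silhouette_,
        linkage_matrix=model.linkage_,
    )


def between_set_sc(matrix, set_a, set_b, scale: bool = True) -> float:
    """Average silhouette treating two disjoint row sets as the two clusters.

    ``matrix`` is a DataFrame indexed by tss_id (or an array with integer
    row ids in set_a/set_b).  Features are z-scaled over the union before
    the correlation distance is computed.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValidationError("both sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValidationError("sets must be disjoint")
    if isinstance(matrix, pd.DataFrame):
        X = matrix.loc[set_a + set_b].to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)[set_a + set_b]
    Z = zscale(X) if scale else X
    D = corr_distance_matrix(Z)
    labels = np.array([0] * len(set_a) + [1] * len(set_b))
    return silhouette(D, labels)[1]


def to_newick(linkage_matrix, leaf_names) -> str:
    """Newick export of a scipy linkage matrix (branch lengths = heights)."""
    tree = hierarchy.to_tree(linkage_matrix)

    def rec(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
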