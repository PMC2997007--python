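"""UPGMA hierarchical clustering of expression profiles.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the closest pair of clusters; the distance from the merged cluster to any
other cluster is the size-weighted average of the member distances, so merge
heights are non-decreasing and the induced cophenetic distances form an
ultrametric.  The agglomeration here is implemented directly (with a
deterministic tie-break: among equally close pairs, merge the one whose
smallest original leaf indices are lexicographically least) rather than
delegated, so that leaf order and dendrogram export are fully specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

METRICS = ("euclidean_log2", "one_minus_pearson")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels and a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric: str = "euclidean_log2"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(v < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v


@dataclass
class Linkage:
    """UPGMA merge history.

    ``records`` holds n-1 rows (child_a, child_b, merge_distance, size) in
    merge order; leaves are clusters 0..n-1 and the k-th merge creates
    cluster n+k.  child_a is always the child containing the smaller
    original leaf index (this fixes the left-to-right leaf order).
    """

    labels: list[str]
    records: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_scipy(self) -> np.ndarray:
        """(n-1, 4) array in scipy.cluster.hierarchy linkage layout."""
        return np.array([[a, b, d, s] for a, b, d, s in self.records], dtype=float)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(
    data: pd.DataFrame, metric: str = "euclidean_log2", already_log2: bool = False
) -> DistanceMatrix:
    """Pairwise distances between the rows of an expression matrix.

    euclidean_log2: Euclidean distance on log2 ratios; one_minus_pearson:
    1 - Pearson correlation of log2 ratios.  ``already_log2`` marks input
    that is a log2 profile set rather than linear ratios.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    X = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite values among selected genes/conditions")
    if not already_log2:
        if np.any(X <= 0):
            raise ValueError("linear ratios must be strictly positive")
        X = np.log2(X)
    labels = [str(x) for x in data.index]
    if metric == "euclidean_log2":
        D = squareform(pdist(X, metric="euclidean"))
    else:
        sd = X.std(axis=1)
        if np.any(sd == 0):
            flat = labels[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"constant profile under Pearson metric: {flat!r}")
        D = squareform(pdist(X, metric="correlation"))
        np.fill_diagonal(D, 0.0)
        D = np.maximum((D + D.T) / 2.0, 0.0)  # guard tiny asymmetries/negatives
    return DistanceMatrix(labels, D, metric)


# ---------------------------------------------------------------------------
# UPGMA agglomeration
# ---------------------------------------------------------------------------

def upgma(D: DistanceMatrix | np.ndarray, labels: Sequence[str] | None = None) -> Linkage:
    """Classic unweighted-average agglomerative clustering.

    O(n^3); the arrays here are small (hundreds of genes at most).
    """
    if isinstance(D, DistanceMatrix):
        dm, labels = D, D.labels
    else:
        arr = np.asarray(D, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        dm = DistanceMatrix(list(labels), arr)
    n = dm.values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")

    # active cluster id -> (size, min original leaf index)
    size = {i: 1 for i in range(n)}
    minleaf = {i: i for i in range(n)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    records: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair, key=lambda c: minleaf[c])
            key = (d, minleaf[i], minleaf[j])
            if best is None or key < best[0]:
                best = (key, i, j)
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        new = next_id
        next_id += 1
        for other in active - {a, b}:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new, other))] = (size[a] * da + size[b] * db) / (
                size[a] + size[b]
            )
        dist.pop(frozenset((a, b)))
        size[new] = size[a] + size[b]
        minleaf[new] = min(minleaf[a], minleaf[b])
        left, right = (a, b) if minleaf[a] <= minleaf[b] else (b, a)
        records.append((left, right, d_ab, size[new]))
        active -= {a, b}
        active.add(new)
    return Linkage(list(dm.labels), records)


def leaf_order(linkage: Linkage) -> list[str]:
    """Deterministic left-to-right dendrogram leaf order."""
    n = linkage.n_leaves
    children = {n + k: (a, b) for k, (a, b, _, _) in enumerate(linkage.records)}
    order: list[str] = []

    def walk(cid: int) -> None:
        if cid < n:
            order.append(linkage.labels[cid])
        else:
            a, b = children[cid]
            walk(a)
            walk(b)

    walk(n + len(linkage.records) - 1)
    return order


def cluster_heights(linkage: Linkage) -> dict[int, float]:
    """Ultrametric node heights: leaves at 0, merges at half the merge distance."""
    heights = {i: 0.0 for i in range(linkage.n_leaves)}
    for k, (_, _, d, _) in enumerate(linkage.records):
        heights[linkage.n_leaves + k] = d / 2.0
    return heights


def to_newick(linkage: Linkage) -> str:
    """Newick string with ultrametric branch lengths (half merge distance)."""
    n = linkage.n_leaves
    children = {n + k: (a, b) for k, (a, b, _, _) in enumerate(linkage.records)}
    heights = cluster_heights(linkage)

    def node(cid: int, parent_height: float) -> str:
        blen = parent_height - heights[cid]
        if cid < n:
            return f"{linkage.labels[cid]}:{blen:.12g}"
        a, b = children[cid]
        h = heights[cid]
        return f"({node(a, h)},{node(b, h)}):{blen:.12g}"

    root = n + len(linkage.records) - 1
    a, b = children[root]
    h = heights[root]
    return f"({node(a, h)},{node(b, h)});"


def cophenetic(linkage: Linkage) -> np.ndarray:
    """Square cophenetic distance matrix (height at which leaves first join)."""
    n = linkage.n_leaves
    members = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for k, (a, b, d, _) in enumerate(linkage.records):
        for i in members[a]:
            for j in members[b]:
                C[i, j] = C[j, i] = d
        members[n + k] = members[a] + members[b]
    return C


def cut_clusters(linkage: Linkage, n_clusters: int) -> np.ndarray:
    """Flat cluster labels obtained by undoing the last n_clusters-1 merges."""
    n = linkage.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    parent = list(range(n + len(linkage.records)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, _, _) in enumerate(linkage.records[: n - n_clusters]):
        root = n + k
        parent[find(a)] = root
        parent[find(b)] = root
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


class UPGMA(ClusterMixin, BaseEstimator):
    """UPGMA clustering as a scikit-learn estimator.

    Parameters
    ----------
    metric : {"euclidean_log2", "one_minus_pearson", "precomputed"}
        Distance between row profiles; "precomputed" expects a square
        distance matrix.
    n_clusters : int
        Number of flat clusters for ``labels_``.
    already_log2 : bool
        Whether the input rows are already log2-transformed profiles.

    Attributes
    ----------
    linkage_ : Linkage
    leaf_order_ : list of str
    newick_ : str
    labels_ : ndarray of shape (n_samples,)
    """

    def __init__(self, metric: str = "euclidean_log2", n_clusters: int = 2,
                 already_log2: bool = False):
        self.metric = metric
        self.n_clusters = n_clusters
        self.already_log2 = already_log2

    def fit(self, X, y=None):
        if self.metric == "precomputed":
            if isinstance(X, DistanceMatrix):
                dm = X
            else:
                labels = [str(i) for i in (X.index if isinstance(X, pd.DataFrame) else range(len(X)))]
                dm = DistanceMatrix(labels, np.asarray(X, dtype=float), "precomputed")
        else:
            if not isinstance(X, pd.DataFrame):
                X = pd.DataFrame(np.asarray(X, dtype=float))
            dm = distance_matrix(X, self.metric, self.already_log2)
        self.distance_matrix_ = dm
        self.linkage_ = upgma(dm)
        self.leaf_order_ = leaf_order(self.linkage_)
        self.newick_ = to_newick(self.linkage_)
        self.labels_ = cut_clusters(self.linkage_, min(self.n_clusters, dm.values.shape[0]))
        self.n_features_in_ = np.asarray(X).shape[1]
        return self
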