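"""Hierarchical clustering of spectral fingerprints and species separation.

Fingerprints (integer bucket-level vectors) are compared by Euclidean
distance and agglomerated with Ward linkage by default — the standard
chemometric choice for binned NMR data — and the dendrogram can be cut into
k groups whose agreement with species labels is summarized as cluster
purity.  Dendrograms export to Newick for external tree viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import Fingerprint

__all__ = [
    "ClusterTree",
    "distance_matrix",
    "hierarchical_cluster",
    "cluster_purity",
    "export_newick",
    "HierarchicalFingerprintClustering",
]


@dataclass
class ClusterTree:
    """An agglomeration history: scipy linkage matrix plus leaf identities."""

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    method: str = "ward"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merges for n leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster assignment (1..k) from cutting the tree into k groups."""
        if k < 1:
            raise ValueError("k must be at least 1")
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def _as_matrix(fps: Sequence) -> np.ndarray:
    rows = [fp.levels if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=float) for fp in fps]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"fingerprints have mismatched lengths: {sorted(lengths)}")
    return np.asarray(rows, dtype=float)


def distance_matrix(fps: Sequence, metric: str = "euclidean") -> np.ndarray:
    """Pairwise distances between fingerprints (symmetric, zero diagonal)."""
    X = _as_matrix(fps)
    return squareform(pdist(X, metric=metric))


def hierarchical_cluster(
    d: np.ndarray,
    linkage: str = "ward",
    leaf_ids: Sequence[str] | None = None,
) -> ClusterTree:
    """Agglomerate a distance matrix into a cluster tree.

    The input must be a valid square distance matrix (symmetric, zero
    diagonal, non-negative).  scipy's agglomeration is deterministic,
    merging the earliest-indexed pair among ties.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    ids = list(leaf_ids) if leaf_ids is not None else [str(i) for i in range(d.shape[0])]
    return ClusterTree(Z, ids, method=linkage)


def cluster_purity(tree: ClusterTree, labels: Sequence[str], k: int) -> float:
    """Fraction of samples in the majority label of their k-cut cluster."""
    labels = np.asarray(labels)
    if labels.size != tree.n_leaves:
        raise ValueError("one label per leaf required")
    assignment = tree.cut(k)
    correct = 0
    for c in np.unique(assignment):
        _, counts = np.unique(labels[assignment == c], return_counts=True)
        correct += counts.max()
    return correct / labels.size


def export_newick(tree: ClusterTree) -> str:
    """Serialize the dendrogram as a Newick string.

    Leaves sit at depth height/2 of their first merge so the tree is
    ultrametric: two leaves merging at height h each get branch length h/2.
    """
    Z = tree.linkage_matrix
    n = tree.n_leaves

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2]) / 2.0

    def render(node: int, parent_h: float) -> str:
        length = parent_h - height(node)
        if node < n:
            return f"{_escape(tree.leaf_ids[node])}:{length:g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{length:g}"

    if n == 1:
        return f"{_escape(tree.leaf_ids[0])}:0;"
    root = 2 * n - 2
    h = height(root)
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({render(left, h)},{render(right, h)});"


def _escape(name: str) -> str:
    if any(c in name for c in " ():,;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


class HierarchicalFingerprintClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of fingerprint matrices, sklearn style.

    Parameters
    ----------
    n_clusters : int
        Number of flat clusters cut from the dendrogram.
    linkage, metric : str
        Agglomeration method and pairwise distance.
    """

    def __init__(self, n_clusters: int = 3, linkage: str = "ward", metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D fingerprint matrix")
        d = distance_matrix(X, metric=self.metric)
        self.tree_ = hierarchical_cluster(d, linkage=self.linkage)
        self.labels_ = self.tree_.cut(self.n_clusters) - 1
        return self

    def purity(self, labels: Sequence[str]) -> float:
        check_is_fitted(self, "tree_")
        return cluster_purity(self.tree_, labels, self.n_clusters)

    def to_newick(self) -> str:
        check_is_fitted(self, "tree_")
        return export_newick(self.tree_)
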