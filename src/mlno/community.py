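"""Modularity-guided phenotype clustering on the similarity network.

Phenotypes are agglomerated by complete-linkage hierarchical clustering
on the dissimilarity 1 - W.  Every cut k0 = 1..K of the dendrogram is
scored by Newman-Girvan modularity

    Q(k0) = (1/2D) * sum_{j,k} (W_jk - d_j d_k / 2D) C_jk,

where d_j = sum_k W_jk, D = sum_j d_j / 2, and C_jk = 1 when j and k
share a cluster.  The sum runs over all ordered pairs including j = k,
so Q is exactly 0 for the one-cluster partition on any W.
:func:`modularity` evaluates this literally on whatever matrix it is
given; :func:`select_clusters` by default zeroes W's unit diagonal
before scoring cuts (see its docstring).  The returned partition
maximizes Q; ties go to the smallest number of clusters.
Clustered phenotypes are merged by the element-wise maximum of their
case indicators, which raises the merged case-control ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ClusterAssignment",
    "hierarchical_cut",
    "modularity",
    "select_clusters",
    "merge_phenotypes",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Phenotype partition: 1-based labels, cluster count L, modularity curve."""

    labels: np.ndarray = field(repr=False)
    n_clusters: int
    modularity_curve: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(1, self.n_clusters + 1)):
            raise ValueError(
                f"labels must cover 1..{self.n_clusters} with no empty cluster"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def modularity(self) -> float | None:
        if self.modularity_curve is None:
            return None
        return float(self.modularity_curve[self.n_clusters - 1])


def _dissimilarity_linkage(W: np.ndarray) -> np.ndarray:
    D = 1.0 - np.asarray(W, dtype=float)
    np.fill_diagonal(D, 0.0)
    # guard tiny negative round-off from the normalization
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return linkage(squareform(D, checks=False), method="complete")


def _relabel(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary labels to 1..L in order of first appearance."""
    _, inverse = np.unique(raw, return_inverse=True)
    first_seen = {}
    labels = np.empty(raw.shape[0], dtype=np.int64)
    for i, g in enumerate(inverse):
        labels[i] = first_seen.setdefault(g, len(first_seen) + 1)
    return labels, len(first_seen)


def hierarchical_cut(W: np.ndarray, k0: int) -> np.ndarray:
    """Complete-linkage clustering of 1 - W, cut to k0 clusters (1-based labels)."""
    K = W.shape[0]
    if not 1 <= k0 <= K:
        raise ValueError(f"cluster count must lie in 1..{K}, got {k0}")
    if k0 == K:
        return np.arange(1, K + 1)
    return _cut_labels(_dissimilarity_linkage(W), K, k0)


def modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity of a labelled partition of the weighted graph W.

    Includes the j = k self-loop terms; Q = 0 exactly for the one-cluster
    partition on any W.
    """
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    two_D = d.sum()
    if two_D <= 0:
        raise ValueError("modularity undefined for an all-zero similarity matrix")
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    B = W - np.outer(d, d) / two_D
    return float(B[same].sum() / two_D)


def select_clusters(W: np.ndarray, include_self_loops: bool = False) -> ClusterAssignment:
    """Score every dendrogram cut by modularity and return the best partition.

    Evaluates Q(k0) for k0 = 1..K on the complete-linkage tree of 1 - W;
    ties in Q break toward fewer clusters.

    By default the unit diagonal of W (each phenotype's self-co-occurrence)
    is excluded when scoring cuts: self-loops carry no information about
    between-phenotype structure, and for extremely sparse co-occurrence
    they dominate the degree sums and push the optimum toward singleton
    clusters.  ``include_self_loops=True`` scores the literal W instead.
    """
    W = np.asarray(W, dtype=float)
    K = W.shape[0]
    if K < 2:
        raise ValueError("need at least two phenotypes to cluster")
    Z = _dissimilarity_linkage(W)
    if not include_self_loops:
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    two_D = d.sum()
    if two_D <= 0:
        raise ValueError("modularity undefined for an all-zero similarity matrix")
    B = W - np.outer(d, d) / two_D
    curve = _modularity_curve(Z, B, two_D, K)
    # argmax with ties toward fewer clusters
    best_L = int(np.argmax(curve)) + 1
    labels = _cut_labels(Z, K, best_L)
    return ClusterAssignment(labels=labels, n_clusters=best_L, modularity_curve=curve)


def _modularity_curve(Z, B, two_D, K):
    """Q at every dendrogram cut, updated merge by merge.

    Merging clusters a and b adds their cross-cluster B mass to the
    within-cluster sum, so Q(L-1) = Q(L) + 2 S_ab / 2D where S tracks
    aggregated B between active clusters.
    """
    S = np.zeros((2 * K - 1, 2 * K - 1))
    S[:K, :K] = B
    curve = np.empty(K)
    q = np.trace(B) / two_D  # K singleton clusters
    curve[K - 1] = q
    for t in range(K - 1):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        q += 2.0 * S[a, b] / two_D
        curve[K - t - 2] = q
        new = K + t
        S[new, : new] = S[a, : new] + S[b, : new]
        S[: new, new] = S[new, : new]
        S[new, new] = S[a, a] + S[b, b] + 2.0 * S[a, b]
    return curve


def _cut_labels(Z, K, n_clusters):
    """Labels (1..n_clusters, first-appearance order) after K - n_clusters merges."""
    parent = np.arange(2 * K - 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t in range(K - n_clusters):
        new = K + t
        parent[find(int(Z[t, 0]))] = new
        parent[find(int(Z[t, 1]))] = new
    raw = np.array([find(j) for j in range(K)])
    labels, _ = _relabel(raw)
    return labels


def merge_phenotypes(phenotypes: np.ndarray, assignment: ClusterAssignment) -> np.ndarray:
    """Merge each cluster of case indicators into one column by element-wise max.

    The merged phenotype is 1 for an individual who is a case for any
    member phenotype, so its case count is at least that of every member.
    """
    Y = np.asarray(phenotypes)
    labels = assignment.labels
    if Y.shape[1] != labels.shape[0]:
        raise ValueError(
            f"phenotype count {Y.shape[1]} does not match labels ({labels.shape[0]})"
        )
    L = assignment.n_clusters
    merged = np.empty((Y.shape[0], L), dtype=Y.dtype)
    for l in range(1, L + 1):
        merged[:, l - 1] = Y[:, labels == l].max(axis=1)
    return merged
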