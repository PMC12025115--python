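"""Agglomerative Ward clustering of compositions in log-ratio geometry.

Samples are embedded in (weighted) log-ratio coordinates, where
Euclidean distance is the (weighted) Aitchison distance, and merged by
Ward's minimum-variance criterion (the Ward.D2 convention: squared
distances in the Lance-Williams update, square roots reported as merge
heights). scipy's hierarchy machinery performs the agglomeration behind
this module's surface.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.utils.validation import check_is_fitted

from .composition import CompositionTable, CompositionError
from .stats import DistanceMatrix, pairwise_distances
from .transforms import PartWeights, clr, weighted_logratio_coords

__all__ = [
    "MergeTree",
    "ward_linkage",
    "cut_tree",
    "select_k",
    "export_dendrogram",
    "WardCompositionClustering",
]


@dataclasses.dataclass
class MergeTree:
    """Result of an agglomeration: merge order, heights, leaf order.

    ``merges`` follows the scipy linkage convention: row t merges nodes
    ``(a, b)`` (leaves are 0..n-1, internal nodes n+t) at ``height``
    into a cluster of ``new_size`` members.
    """

    leaf_ids: list[str]
    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, new_size

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise CompositionError(
                f"expected {n - 1} merges for {n} leaves, got {self.merges.shape}"
            )
        if self.merges.shape[0] and self.merges[-1, 3] != n:
            raise CompositionError("final merge must contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        """Leaf permutation for crossing-free dendrogram plotting."""
        return hierarchy.leaves_list(self.merges).tolist()


def ward_linkage(dm: DistanceMatrix) -> MergeTree:
    """Ward.D2 agglomeration of a metric distance matrix.

    Uses the Lance-Williams update on squared distances,
    d(AB,C)^2 = ((nA+nC) d(A,C)^2 + (nB+nC) d(B,C)^2 - nC d(A,B)^2)
                / (nA+nB+nC),
    reporting sqrt of the merge cost as the height; heights are
    non-decreasing for metric inputs. Deterministic given the input
    order.
    """
    if dm.n < 2:
        raise CompositionError("clustering needs at least 2 samples")
    Z = hierarchy.linkage(dm.condensed(), method="ward")
    return MergeTree(list(dm.ids), Z)


def cut_tree(tree: MergeTree, k: int) -> pd.Series:
    """Cut the tree into ``k`` groups.

    Returns a Series mapping sample id to cluster label; labels are
    "C1", "C2", ... ordered by decreasing group size (ties broken by the
    first sample id in the group).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise CompositionError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise CompositionError(
            f"tree does not admit a cut into exactly {k} groups (tied heights)"
        )
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(raw):
        groups.setdefault(int(g), []).append(i)
    ordered = sorted(
        groups.values(), key=lambda idx: (-len(idx), tree.leaf_ids[idx[0]])
    )
    labels = np.empty(n, dtype=object)
    for rank, idx in enumerate(ordered):
        for i in idx:
            labels[i] = f"C{rank + 1}"
    return pd.Series(labels, index=pd.Index(tree.leaf_ids, name="sample_id"), name="cluster")


def select_k(
    table: CompositionTable,
    tree: MergeTree,
    k_range: Sequence[int] | range = range(2, 9),
    criterion: str = "silhouette",
    weights: PartWeights | None = None,
) -> tuple[int, pd.DataFrame]:
    """Advisory choice of the number of clusters.

    Scores each cut of ``tree`` for k in ``k_range`` in the same metric
    the clustering used (silhouette on the precomputed weighted
    log-ratio distances, or Calinski-Harabasz on the coordinates) and
    returns the arg-max together with the full per-k score table.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise CompositionError("empty k range")
    n = tree.n_leaves
    if min(ks) < 2 or max(ks) > n - 1:
        raise CompositionError(f"k range must lie within [2, {n - 1}]")
    coords = (
        clr(table) if weights is None else weighted_logratio_coords(table, weights)
    )
    if np.allclose(np.var(coords, axis=0), 0):
        raise CompositionError(
            "all samples identical: cluster-number criteria are undefined"
        )
    dmat = pairwise_distances(table, weights).d
    rows = []
    for k in ks:
        lab = cut_tree(tree, k).to_numpy()
        if criterion == "silhouette":
            score = silhouette_score(dmat, lab, metric="precomputed")
        elif criterion == "calinski":
            score = calinski_harabasz_score(coords, lab)
        else:
            raise CompositionError(f"unknown criterion {criterion!r}")
        rows.append({"k": k, "score": float(score)})
    scores = pd.DataFrame(rows)
    best = int(scores.loc[scores["score"].idxmax(), "k"])
    return best, scores


def export_dendrogram(tree: MergeTree) -> str:
    """Serialize the merge tree as a Newick string with branch lengths.

    Node heights follow the R ``as.phylo(hclust)`` convention: a node
    created by a merge at height h sits at height h/2, leaves at 0, and
    a branch length is the parent-child height difference — so two
    leaves merged at height h serialize as ``(A:h/2,B:h/2);``.
    """
    n = tree.n_leaves
    if n == 1:
        return f"{tree.leaf_ids[0]}:0;"
    node_height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for t, (a, b, h, _) in enumerate(tree.merges):
        node = n + t
        node_height[node] = h / 2.0
        children[node] = (int(a), int(b))

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - node_height[node]
        if node < n:
            return f"{tree.leaf_ids[node]}:{bl:.10g}"
        a, b = children[node]
        h = node_height[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

    root = n + len(children) - 1
    a, b = children[root]
    h = node_height[root]
    return f"({render(a, h)},{render(b, h)});"


class WardCompositionClustering(ClusterMixin, BaseEstimator):
    """Ward clustering of compositions with a weighted log-ratio metric.

    Parameters
    ----------
    n_clusters : int, default 3
        Number of groups the tree is cut into.
    weighting : {"table", "uniform"}, default "table"
        "table" uses column-mean proportions of the fitted table as part
        weights (the weighted log-ratio convention); "uniform" reduces
        the metric to the classic Aitchison distance up to a constant
        factor.

    Attributes
    ----------
    weights_ : PartWeights
    distance_matrix_ : DistanceMatrix
    tree_ : MergeTree
    labels_ : ndarray of str cluster labels ("C1" largest, ...)
    """

    def __init__(self, n_clusters: int = 3, weighting: str = "table"):
        self.n_clusters = n_clusters
        self.weighting = weighting

    def _as_table(self, X) -> CompositionTable:
        if isinstance(X, CompositionTable):
            return X
        X = np.asarray(X, dtype=float)
        return CompositionTable(
            [f"s{i}" for i in range(X.shape[0])],
            [f"p{j}" for j in range(X.shape[1])],
            X,
        )

    def fit(self, X, y=None):
        table = self._as_table(X)
        if self.weighting == "table":
            self.weights_ = PartWeights.from_table(table)
        elif self.weighting == "uniform":
            self.weights_ = PartWeights.uniform(table.part_names)
        else:
            raise CompositionError(f"unknown weighting {self.weighting!r}")
        self.distance_matrix_ = pairwise_distances(table, self.weights_)
        self.tree_ = ward_linkage(self.distance_matrix_)
        assignment = cut_tree(self.tree_, self.n_clusters)
        self.assignment_ = assignment
        self.labels_ = assignment.to_numpy()
        self.n_features_in_ = table.n_parts
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
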