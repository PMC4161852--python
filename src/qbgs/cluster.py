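"""Unsupervised view of a methylation matrix: Ward clustering + survival.

Hierarchical clustering with the Ward criterion on raw (unstandardised)
methylation proportions groups samples by overall promoter methylation level;
cutting the tree at k = 4 mirrors the strongly / moderately / slightly /
almost-un-methylated archetypes seen in promoter methylation cohorts.
Clusters are relabelled 1..k by *descending* mean methylation so that
cluster 1 is always the most methylated group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .quant import MethylationMatrix
from .survival import SurvivalTable, logrank

__all__ = ["ClusterResult", "ward_clusters", "pairwise_survival", "to_newick"]


@dataclass
class ClusterResult:
    """A Ward merge tree plus a flat cut at k clusters."""

    linkage: np.ndarray
    labels: np.ndarray  # cluster id (1..k) per sample, matrix row order
    k: int
    sample_ids: list[str]

    def members(self, cluster_id: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == cluster_id]


def ward_clusters(
    matrix: MethylationMatrix, k: int, dialect: str = "D2"
) -> ClusterResult:
    """Ward hierarchical clustering of samples on raw proportions, cut at k.

    ``dialect`` selects the Ward flavour: ``"D2"`` (default) is Ward on
    Euclidean distances (scipy's native ``ward``, the Ward.D2 convention);
    ``"D"`` emulates the classic Ward.D recurrence by feeding the Lance-
    Williams update the unsquared distances.  Missing cells must be imputed
    or dropped beforehand.
    """
    X = matrix.proportions.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix has missing cells; impute or drop before clustering")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} not in [1, {n}]")
    if dialect == "D2":
        Z = linkage(X, method="ward")
    elif dialect == "D":
        # scipy's recurrence squares its input internally, so feeding sqrt(d)
        # reproduces the Ward.D update on the raw Euclidean distances.
        Z = linkage(np.sqrt(pdist(X)), method="ward")
    else:
        raise ValueError("dialect must be 'D' or 'D2'")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel by descending mean methylation: 1 = most methylated
    means = {c: X[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=means.get, reverse=True)
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[c] for c in raw])
    return ClusterResult(Z, labels, k=len(order), sample_ids=matrix.sample_ids)


def pairwise_survival(result: ClusterResult, surv: SurvivalTable) -> pd.DataFrame:
    """All-pairs two-group log-rank p-values among clusters (no correction).

    Returns a symmetric k x k DataFrame with NaN on the diagonal.
    """
    surv = surv.align(result.sample_ids)
    ids = np.unique(result.labels)
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            _, p = logrank(surv.mask(result.labels == a), surv.mask(result.labels == b))
            out.loc[a, b] = out.loc[b, a] = p
    return out


def to_newick(result: ClusterResult) -> str:
    """Export the merge tree as a Newick string with merge heights as lengths."""
    tree = to_tree(result.linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.sample_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
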