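"""Subpopulation relatedness and marker-gene ranking.

``build_cluster_tree`` summarizes each cluster by its mean expression
profile over a gene set and joins the profiles by average-linkage
agglomeration on Euclidean distance, yielding the correlation-tree view of
subpopulation relatedness (exportable as Newick).

``rank_markers`` contrasts two cell groups gene-by-gene with a two-sided
Wilcoxon rank-sum test, Benjamini–Hochberg adjusted, and reports the log
fold change of the de-logged mean expression,
avg_logFC = log(mean(expm1 x_high) + 1) − log(mean(expm1 x_low) + 1),
keeping genes with |avg_logFC| above a cutoff (default 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterTree", "build_cluster_tree", "rank_markers"]


@dataclass(frozen=True)
class ClusterTree:
    """Average-linkage tree over cluster mean-expression profiles."""

    linkage: np.ndarray
    cluster_ids: list
    profiles: pd.DataFrame  # clusters × genes mean expression

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, [str(c) for c in self.cluster_ids])
        return str(tree)


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def build_cluster_tree(
    X,
    labels,
    gene_names: Sequence[str],
    gene_set: Sequence[str] | None = None,
) -> ClusterTree:
    """Agglomerate clusters by mean expression over ``gene_set``.

    ``X`` is the normalized cells × genes matrix.  ``gene_set`` defaults to
    all genes (callers usually pass the variable genes).  Requires >= 2
    clusters; deterministic, and invariant to cell order within clusters.
    """
    X = _dense(X)
    labels = np.asarray(labels)
    gene_index = pd.Index(gene_names)
    if gene_set is None:
        cols = np.arange(len(gene_index))
        genes = list(gene_index)
    else:
        genes = [g for g in gene_set if g in gene_index]
        if not genes:
            raise ValueError("gene_set has no genes in the matrix")
        cols = np.array([gene_index.get_loc(g) for g in genes])

    cluster_ids = sorted(pd.unique(labels), key=str)
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters to build a tree")
    profiles = np.vstack([X[labels == c][:, cols].mean(axis=0) for c in cluster_ids])
    Z = average(pdist(profiles, metric="euclidean"))
    return ClusterTree(
        linkage=Z,
        cluster_ids=list(cluster_ids),
        profiles=pd.DataFrame(profiles, index=pd.Index(cluster_ids, name="cluster"), columns=genes),
    )


def rank_markers(
    X,
    gene_names: Sequence[str],
    high_idx,
    low_idx,
    logfc_cutoff: float = 0.25,
    base: str = "e",
) -> pd.DataFrame:
    """Differential genes between a high and a low cell group.

    Returns a DataFrame (gene, avg_logFC, p_value, p_adj, direction) for
    genes passing ``|avg_logFC| > logfc_cutoff``, sorted by |avg_logFC|
    descending then p_adj ascending.  BH adjustment runs across all tested
    genes before the cutoff.  ``base`` is "e" (natural log, default) or
    "2"; the fold-change base is recorded in ``df.attrs["logfc_base"]``.
    """
    X = _dense(X)
    high_idx = np.asarray(high_idx)
    low_idx = np.asarray(low_idx)
    if high_idx.dtype == bool:
        high_idx = np.flatnonzero(high_idx)
    if low_idx.dtype == bool:
        low_idx = np.flatnonzero(low_idx)
    if high_idx.size < 3 or low_idx.size < 3:
        raise ValueError("both groups need at least 3 cells")
    if np.intersect1d(high_idx, low_idx).size:
        raise ValueError("groups must be disjoint")
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' or '2'")

    Xh, Xl = X[high_idx], X[low_idx]
    mean_h = np.expm1(Xh).mean(axis=0)
    mean_l = np.expm1(Xl).mean(axis=0)
    logfc = np.log(mean_h + 1.0) - np.log(mean_l + 1.0)
    if base == "2":
        logfc = logfc / np.log(2.0)

    res = mannwhitneyu(Xh, Xl, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue)
    # Constant genes give undefined ranks; their association is null.
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    df = pd.DataFrame(
        {
            "gene": list(gene_names),
            "avg_logFC": logfc,
            "p_value": pvals,
            "p_adj": p_adj,
            "direction": np.where(logfc > 0, "up", "down"),
        }
    )
    df = df[np.abs(df["avg_logFC"]) > logfc_cutoff]
    df = df.sort_values(
        ["avg_logFC", "p_adj"], key=lambda s: -np.abs(s) if s.name == "avg_logFC" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    df.attrs["logfc_base"] = base
    return df
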