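"""Cluster-resolution scoring against treatment origin.

Three complementary scores decide how many clusters resolve the treatment
arms without over-splitting:

* **entropy score** — the origin-label Shannon entropy within clusters,
  cluster-size weighted and normalized by the global origin entropy:

      E = [ -Σ_i f_i Σ_j d_ji ln d_ji ] / [ -Σ_j f_j ln f_j ]

  where f_i is the fraction of cells in cluster i, f_j the fraction of
  cells from origin j, and d_ji the fraction of origin j within cluster i.
  E = 0 when every cluster is origin-pure (origins fully resolved); E = 1
  when all cells sit in one cluster.

* **Monte-Carlo Fisher exact test** — repeated 150-cell downsampling of the
  cluster × origin table with a permutation p-value under fixed margins,
  summarized as mean ± SE over repeats (the primary criterion).

* **mean silhouette** — origin-blind cluster cohesion/separation with
  Euclidean distance on the 2-D embedding.

The selection rule takes the silhouette-optimal cluster number k* and,
within the window [k*, 3k*], picks the smallest cluster number achieving
the minimal mean Fisher p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.metrics import silhouette_samples

__all__ = [
    "OriginClusterTable",
    "entropy_score",
    "fisher_resample",
    "mean_silhouette",
    "select_cluster_number",
]


@dataclass(frozen=True)
class OriginClusterTable:
    """A clusters × origins contingency table with derived fractions."""

    counts: pd.DataFrame  # index: cluster ids, columns: origin names

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if c.ndim != 2 or np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be a non-negative integer table")

    @classmethod
    def from_labels(cls, labels, origins) -> "OriginClusterTable":
        labels = np.asarray(labels)
        origins = np.asarray(origins)
        if labels.shape != origins.shape:
            raise ValueError("labels and origins must have equal length")
        return cls(pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(origins, name="origin")))

    @property
    def n_cells(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def f_i(self) -> np.ndarray:
        """Fraction of cells in each cluster."""
        c = self.counts.to_numpy()
        return c.sum(axis=1) / c.sum()

    @property
    def f_j(self) -> np.ndarray:
        """Fraction of cells from each origin."""
        c = self.counts.to_numpy()
        return c.sum(axis=0) / c.sum()

    @property
    def d_ji(self) -> np.ndarray:
        """Within-cluster origin fractions, rows = clusters (rows sum to 1)."""
        c = self.counts.to_numpy().astype(float)
        row = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, c / row, 0.0)


def _xlogx(p: np.ndarray) -> np.ndarray:
    # 0 * ln 0 := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p > 0, p * np.log(p), 0.0)


def entropy_score(table: OriginClusterTable) -> float:
    """Normalized weighted within-cluster origin entropy, in [0, 1]."""
    f_j = table.f_j
    if np.count_nonzero(f_j) < 2:
        raise ValueError("entropy score needs at least 2 origins with cells")
    numerator = -np.sum(table.f_i[:, None] * _xlogx(table.d_ji))
    denominator = -np.sum(_xlogx(f_j))
    return float(numerator / denominator)


def _table_logprob(counts: np.ndarray, lgf: np.ndarray) -> float:
    """Log-probability of an r×c table under fixed margins (hypergeometric)."""
    n = counts.sum()
    return float(
        lgf[counts.sum(axis=1)].sum()
        + lgf[counts.sum(axis=0)].sum()
        - lgf[n]
        - lgf[counts].sum()
    )


def fisher_resample(
    labels,
    origins,
    n_cells: int = 150,
    n_repeats: int = 100,
    n_mc_tables: int = 2000,
    seed: int = 0,
    return_pvalues: bool = False,
):
    """Monte-Carlo Fisher exact test of cluster/origin association.

    Each repeat draws ``n_cells`` cells uniformly without replacement,
    builds the cluster × origin table, and computes a permutation p-value:
    origins are shuffled ``n_mc_tables`` times (fixing both margins in
    expectation of the exact-test null) and a permuted table counts as at
    least as extreme when its fixed-margins hypergeometric log-probability
    does not exceed the observed one.  p = (1 + #extreme) / (n_mc_tables+1).
    Degenerate subsamples (a single cluster or origin) score p = 1.
    Returns the mean and standard error of the p-values over repeats
    (plus the per-repeat p-values when ``return_pvalues`` is set).
    """
    labels = np.asarray(labels)
    origins = np.asarray(origins)
    n = labels.size
    if n < n_cells:
        raise ValueError(f"need at least {n_cells} cells, have {n}")

    _, lab_codes = np.unique(labels, return_inverse=True)
    _, org_codes = np.unique(origins, return_inverse=True)
    n_lab = lab_codes.max() + 1
    n_org = org_codes.max() + 1
    lgf = gammaln(np.arange(n_cells + 1) + 1.0)
    rng = np.random.default_rng(seed)

    pvals = np.empty(n_repeats)
    for r in range(n_repeats):
        idx = rng.choice(n, size=n_cells, replace=False)
        lab = lab_codes[idx]
        org = org_codes[idx]
        if np.unique(lab).size < 2 or np.unique(org).size < 2:
            pvals[r] = 1.0
            continue
        obs = np.bincount(lab * n_org + org, minlength=n_lab * n_org).reshape(n_lab, n_org)
        lp_obs = _table_logprob(obs, lgf)
        extreme = 0
        for _ in range(n_mc_tables):
            perm = rng.permutation(org)
            t = np.bincount(lab * n_org + perm, minlength=n_lab * n_org).reshape(n_lab, n_org)
            if _table_logprob(t, lgf) <= lp_obs + 1e-9:
                extreme += 1
        pvals[r] = (1 + extreme) / (n_mc_tables + 1)

    mean_p = float(pvals.mean())
    se_p = float(pvals.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    if return_pvalues:
        return mean_p, se_p, pvals
    return mean_p, se_p


def mean_silhouette(coords2d: np.ndarray, labels) -> float:
    """Mean silhouette with Euclidean distance on the 2-D embedding.

    Singleton clusters contribute silhouette 0.  A single-cluster labeling
    is a domain error.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_samples(np.asarray(coords2d), labels).mean())


def select_cluster_number(scan: pd.DataFrame) -> dict:
    """Choose the cluster number from a resolution scan.

    ``scan`` rows carry ``resolution``, ``n_clusters``, ``entropy_score``,
    ``fisher_mean_p``, ``fisher_se_p``, ``mean_silhouette``.  Let k* be the
    cluster number with maximal mean silhouette (smallest k on ties).
    Among rows with k* <= n_clusters <= 3 k*, the row with minimal
    ``fisher_mean_p`` wins (ties: lower entropy score, then lower
    n_clusters).  An empty window falls back to the global Fisher optimum
    with a warning recorded in the audit trail.
    """
    required = {"n_clusters", "entropy_score", "fisher_mean_p", "mean_silhouette"}
    if scan.empty or not required <= set(scan.columns):
        raise ValueError("scan must be non-empty with the scoring columns")

    sil_best = scan["mean_silhouette"].max()
    k_star = int(scan.loc[scan["mean_silhouette"] == sil_best, "n_clusters"].min())
    window = scan[(scan["n_clusters"] >= k_star) & (scan["n_clusters"] <= 3 * k_star)]

    audit = {"k_silhouette": k_star, "window": (k_star, 3 * k_star), "fallback": False}
    if window.empty:
        audit["fallback"] = True
        window = scan

    ordered = window.sort_values(
        ["fisher_mean_p", "entropy_score", "n_clusters"], kind="mergesort"
    )
    chosen = ordered.iloc[0]
    audit["fisher_min_p"] = float(chosen["fisher_mean_p"])
    return {"row": chosen, "n_clusters": int(chosen["n_clusters"]), "audit": audit}
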