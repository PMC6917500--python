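"""scRNA-seq QC, normalization, embedding and cell-cycle stage assignment.

The in-memory container is an :class:`anndata.AnnData` holding raw UMI
counts (``layers["counts"]``), normalized expression (``X`` after
:func:`normalize_log`), per-cell QC metrics and the treatment-origin label
in ``obs``.  The processing chain mirrors the standard droplet workflow:

    counts → filter_cells → normalize_log → select_hvg → scale_and_regress
           → pca_embed → knn_snn_cluster / embed_2d

with an additional cell-cycle layer: each cell is scored for S-phase and
G2/M-phase marker expression against bin-matched background genes, and
assigned to G0/G1, S or G2/M before any subpopulation clustering, so that
cycle transcription does not dominate the cluster structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DEFAULT_S_GENES",
    "DEFAULT_G2M_GENES",
    "CellCycleScores",
    "make_count_matrix",
    "filter_cells",
    "normalize_log",
    "select_hvg",
    "scale_and_regress",
    "pca_embed",
    "knn_snn_cluster",
    "embed_2d",
    "cell_cycle_scores",
    "assign_stage",
]

# Widely used S-phase / G2M-phase marker panels (human symbols). Overridable
# in every scoring call; synthetic tests supply their own designated lists.
DEFAULT_S_GENES = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "CENPU", "HELLS", "RFC2",
    "RPA2", "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7",
    "POLD3", "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1",
    "TIPIN", "DSCC1", "BLM", "CASP8AP2", "USP1", "CLSPN", "POLA1", "CHAF1B",
    "BRIP1", "E2F8",
]
DEFAULT_G2M_GENES = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "PIMREG",
    "SMC4", "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "JPT1", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "CTCF", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
]

STAGES = ("G0/G1", "S", "G2/M")


@dataclass(frozen=True)
class CellCycleScores:
    """Per-cell S-phase and G2/M-phase scores (marker minus control mean)."""

    s_score: np.ndarray
    g2m_score: np.ndarray

    def __post_init__(self) -> None:
        if self.s_score.shape != self.g2m_score.shape:
            raise ValueError("score vectors must have equal length")
        if not (np.all(np.isfinite(self.s_score)) and np.all(np.isfinite(self.g2m_score))):
            raise ValueError("scores must be finite")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def make_count_matrix(
    counts,
    gene_names: Sequence[str],
    cell_barcodes: Sequence[str],
    origin: Sequence[str],
    mito_prefix: str = "MT-",
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL"),
) -> ad.AnnData:
    """Assemble an AnnData of raw UMI counts with per-cell QC metrics.

    ``counts`` is cells × genes (dense or sparse, non-negative integers).
    Adds ``obs`` columns ``origin``, ``n_genes``, ``total_umi``,
    ``pct_mito``, ``pct_ribo`` and stores the raw counts in
    ``layers["counts"]``.  Mitochondrial and ribosomal genes are identified
    by configurable name prefixes.
    """
    X = sp.csr_matrix(counts)
    if X.shape != (len(cell_barcodes), len(gene_names)):
        raise ValueError("counts shape inconsistent with barcodes/gene names")
    if len(origin) != len(cell_barcodes):
        raise ValueError("origin must be defined for every cell")
    if X.nnz and (X.data < 0).any():
        raise ValueError("counts must be non-negative")

    adata = ad.AnnData(
        X=X.astype(np.float32),
        obs=pd.DataFrame(index=pd.Index(cell_barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.obs["origin"] = pd.Categorical(origin)

    genes = pd.Index(gene_names)
    is_mito = genes.str.upper().str.startswith(mito_prefix.upper())
    is_ribo = genes.str.upper().str.startswith(tuple(p.upper() for p in ribo_prefixes))
    adata.var["mito"] = np.asarray(is_mito)
    adata.var["ribo"] = np.asarray(is_ribo)

    total = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["total_umi"] = total
    adata.obs["n_genes"] = np.asarray((X > 0).sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["pct_mito"] = np.where(
            total > 0, np.asarray(X[:, np.asarray(is_mito)].sum(axis=1)).ravel() / total, 0.0
        )
        adata.obs["pct_ribo"] = np.where(
            total > 0, np.asarray(X[:, np.asarray(is_ribo)].sum(axis=1)).ravel() / total, 0.0
        )
    return adata


def filter_cells(
    adata: ad.AnnData,
    min_genes: int = 1000,
    max_genes: int = 5000,
    max_mito: float = 0.20,
) -> ad.AnnData:
    """Keep cells with min_genes <= n_genes <= max_genes and pct_mito < max_mito.

    Gene bounds are inclusive; the mitochondrial bound is strict.
    """
    keep = (
        (adata.obs["n_genes"] >= min_genes)
        & (adata.obs["n_genes"] <= max_genes)
        & (adata.obs["pct_mito"] < max_mito)
    ).to_numpy()
    if not keep.any():
        raise ValueError("quality filter removed every cell")
    return adata[keep].copy()


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: x → ln(1 + count/total · scale).

    Operates in place on ``adata.X`` (raw counts stay in
    ``layers["counts"]``) and returns the same object.
    """
    counts = adata.layers.get("counts", adata.X)
    total = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(total <= 0):
        raise ValueError("every cell must have a positive UMI total")
    X = sp.csr_matrix(counts, dtype=np.float64)
    X = sp.diags(scale / total) @ X
    X.data = np.log1p(X.data)
    adata.X = X.astype(np.float32)
    adata.uns["normalized"] = {"scale": scale}
    return adata


def select_hvg(
    adata: ad.AnnData,
    n_bins: int = 20,
    z_cutoff: float = 1.0,
    mean_bounds: tuple[float, float] = (0.0125, 8.0),
) -> list[str]:
    """Highly variable genes by binned-dispersion z-score.

    Per gene, on the de-logged (expm1) normalized values: mean µ and
    dispersion σ²/µ.  Genes are binned by log1p(µ) into ``n_bins`` equal-width
    bins and the dispersion z-scored within each bin; genes with z above
    ``z_cutoff`` and log1p(µ) inside ``mean_bounds`` are returned.
    """
    if adata.n_vars < n_bins:
        raise ValueError("fewer genes than bins")
    X = _dense(adata.X)
    E = np.expm1(X)
    mu = E.mean(axis=0)
    var = E.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    log_mu = np.log1p(mu)

    df = pd.DataFrame({"log_mu": log_mu, "disp": disp}, index=adata.var_names)
    df["bin"] = pd.cut(df["log_mu"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    center = grouped.transform("mean")
    spread = grouped.transform("std")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (df["disp"] - center) / spread
    z = z.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    selected = (z > z_cutoff) & (df["log_mu"] >= mean_bounds[0]) & (df["log_mu"] <= mean_bounds[1])
    return list(df.index[selected])


def scale_and_regress(
    adata: ad.AnnData,
    genes: Sequence[str] | None = None,
    covariates: Sequence[str] = ("total_umi", "pct_mito", "pct_ribo"),
    clip: float = 10.0,
) -> np.ndarray:
    """Regress per-cell covariates out of each gene, then z-score and clip.

    Per gene: OLS residuals of the normalized expression against the named
    ``obs`` covariates (with intercept), standardized to unit variance and
    clipped at ±``clip``.  An empty covariate list gives a plain per-gene
    z-score.  Returns a dense cells × genes array ordered like ``genes``.
    """
    if genes is None:
        genes = list(adata.var_names)
    Y = _dense(adata[:, list(genes)].X).astype(np.float64)

    if covariates:
        C = adata.obs[list(covariates)].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(C)):
            raise ValueError("covariates must be finite")
        X = np.column_stack([np.ones(len(C)), C])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
    else:
        R = Y - Y.mean(axis=0)

    sd = R.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (R - R.mean(axis=0)) / sd
    return np.clip(Z, -clip, clip)


def pca_embed(scaled: np.ndarray, n_components: int = 20) -> np.ndarray:
    """PCA scores with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive,
    making the embedding reproducible across runs and BLAS backends.
    """
    n_components = min(n_components, min(scaled.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(scaled)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1.0
    return scores


def _knn_indices(embedding: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    return nn.kneighbors(return_distance=False)


def knn_snn_cluster(
    embedding: np.ndarray,
    k: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> np.ndarray:
    """Shared-nearest-neighbor graph clustering on a PCA embedding.

    Builds a kNN graph, reweights each edge by the Jaccard overlap of the
    two endpoints' neighbor sets (edges below ``prune`` dropped), and
    partitions the graph by Leiden modularity optimization at the given
    resolution.  Deterministic given the seed.  The backend is
    intentionally pluggable: downstream scoring consumes labels only.
    """
    import igraph
    import leidenalg

    n = embedding.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nbrs = _knn_indices(embedding, k)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(nbrs)]

    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    seen: set[tuple[int, int]] = set()
    for i, row in enumerate(nbrs):
        for j in row:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a == b or (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            w = inter / union
            if w >= prune:
                edges.append((a, b))
                weights.append(w)

    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    return np.asarray(part.membership)


def embed_2d(embedding: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Seed-deterministic 2-D t-SNE layout of a PCA embedding."""
    n = embedding.shape[0]
    if n < 5:
        raise ValueError("need at least 5 cells for a 2-D layout")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca", random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tsne.fit_transform(embedding)


def _score_gene_set(
    X: np.ndarray,
    gene_index: pd.Index,
    markers: list[str],
    n_bins: int,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    mean_expr = X.mean(axis=0)
    # Quantile bins of average expression over all genes; every marker draws
    # its controls (with replacement) from its own bin.
    order = pd.Series(mean_expr, index=gene_index).rank(method="first")
    bins = pd.qcut(order, q=n_bins, labels=False, duplicates="drop")
    marker_pos = np.array([gene_index.get_loc(g) for g in markers])

    ctrl_pos: list[np.ndarray] = []
    for pos in marker_pos:
        pool = np.flatnonzero(bins.to_numpy() == bins.iloc[pos])
        ctrl_pos.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_pos)
    return X[:, marker_pos].mean(axis=1) - X[:, ctrl].mean(axis=1)


def cell_cycle_scores(
    adata: ad.AnnData,
    s_genes: Sequence[str] | None = None,
    g2m_genes: Sequence[str] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellCycleScores:
    """Score each cell for S and G2/M marker expression against background.

    Per marker set and cell: mean expression of the markers minus the mean
    of bin-matched control genes (``n_ctrl`` controls per marker, drawn with
    replacement from the marker's average-expression bin).  Markers missing
    from the matrix are dropped with a warning; an empty set is an error.
    """
    s_genes = list(DEFAULT_S_GENES if s_genes is None else s_genes)
    g2m_genes = list(DEFAULT_G2M_GENES if g2m_genes is None else g2m_genes)
    gene_index = pd.Index(adata.var_names)
    X = _dense(adata.X)
    rng = np.random.default_rng(seed)

    scores = []
    for name, markers in (("S", s_genes), ("G2/M", g2m_genes)):
        present = [g for g in markers if g in gene_index]
        missing = len(markers) - len(present)
        if missing:
            warnings.warn(f"{missing} {name} marker gene(s) not in matrix; dropped", stacklevel=2)
        if not present:
            raise ValueError(f"no {name} marker genes present in the matrix")
        scores.append(_score_gene_set(X, gene_index, present, n_bins, n_ctrl, rng))
    return CellCycleScores(s_score=scores[0], g2m_score=scores[1])


def assign_stage(scores: CellCycleScores) -> np.ndarray:
    """Assign each cell to G0/G1, S or G2/M from its cycle scores.

    Both scores non-positive → G0/G1 (non-cycling).  Otherwise the larger
    score wins, with S taking equal positive scores.
    """
    s, g2m = scores.s_score, scores.g2m_score
    out = np.full(s.shape, "G0/G1", dtype=object)
    cycling = (s > 0) | (g2m > 0)
    out[cycling & (s >= g2m)] = "S"
    out[cycling & (g2m > s)] = "G2/M"
    return out
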