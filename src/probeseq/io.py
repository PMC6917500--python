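"""Readers and writers for the plain-text formats the package consumes.

Count matrices arrive either as a 10x-style sparse triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, genes × cells as
written by 10x tooling) or as a dense CSV (cells × genes, first column the
cell barcode).  The per-cell treatment origin comes from a sidecar TSV
(columns ``barcode``, ``origin``) or a same-order single-column file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import anndata as ad
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .preprocess import make_count_matrix

__all__ = ["read_counts_mtx", "read_counts_csv", "read_origin_tsv", "write_counts_mtx"]


def read_origin_tsv(path: str | Path, barcodes: Sequence[str]) -> list[str]:
    """Per-cell origin labels, keyed by barcode when a header is present."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] >= 2:
        first = df.iloc[0].tolist()
        if "barcode" in [str(v).lower() for v in first]:
            df = pd.read_csv(path, sep="\t", dtype=str)
            df.columns = [c.lower() for c in df.columns]
            mapping = dict(zip(df["barcode"], df["origin"]))
        else:
            mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        missing = [b for b in barcodes if b not in mapping]
        if missing:
            raise ValueError(f"{len(missing)} barcode(s) missing from origin file")
        return [mapping[b] for b in barcodes]
    if len(df) != len(barcodes):
        raise ValueError("single-column origin file must match cell count")
    return df.iloc[:, 0].tolist()


def read_counts_mtx(
    directory: str | Path,
    origin: str | Path | Sequence[str],
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Load a 10x-style triplet directory (genes × cells) into an AnnData."""
    d = Path(directory)
    mat = sp.csr_matrix(mmread(str(d / "matrix.mtx")))
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None).iloc[:, -1].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].tolist()
    counts = mat.T  # stored genes × cells
    if isinstance(origin, (str, Path)):
        origin = read_origin_tsv(origin, barcodes)
    return make_count_matrix(counts, genes, barcodes, list(origin), mito_prefix=mito_prefix)


def read_counts_csv(
    path: str | Path,
    origin: str | Path | Sequence[str],
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Load a dense cells × genes CSV (first column = barcode)."""
    df = pd.read_csv(path, index_col=0)
    barcodes = df.index.astype(str).tolist()
    if isinstance(origin, (str, Path)):
        origin = read_origin_tsv(origin, barcodes)
    return make_count_matrix(
        df.to_numpy(), df.columns.tolist(), barcodes, list(origin), mito_prefix=mito_prefix
    )


def write_counts_mtx(adata: ad.AnnData, directory: str | Path) -> None:
    """Write counts as a 10x-style triplet directory plus an origin TSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(counts.T).astype(int))
    pd.Series(adata.var_names).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": adata.obs_names, "origin": adata.obs["origin"].astype(str)}).to_csv(
        d / "origins.tsv", sep="\t", index=False
    )
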