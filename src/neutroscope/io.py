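"""Portable on-disk dialects: 10x-style MatrixMarket triplets and
metadata-stamped CSV tables.

The triplet layout is ``matrix.mtx`` (MatrixMarket coordinate, genes x
cells, 1-based indices), ``features.tsv`` and ``barcodes.tsv``
line-aligned with the matrix dimensions; ``.gz`` variants are read
transparently. Tabular outputs are plain CSV preceded by ``#`` comment
lines carrying the package version, seed and configuration hash so every
artifact records its provenance.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def write_matrix_10x(counts, dirpath, gene_ids=None, barcodes=None) -> None:
    """Write counts (AnnData cells x genes, or genes x cells sparse) as a
    10x-style triplet directory."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    if hasattr(counts, "X"):
        M = sp.csc_matrix(counts.X.T)  # genes x cells on disk
        gene_ids = list(counts.var_names)
        barcodes = list(counts.obs_names)
    else:
        M = sp.csc_matrix(counts)
        if gene_ids is None or barcodes is None:
            raise ValueError("gene_ids and barcodes are required for raw matrices")
    if M.shape != (len(gene_ids), len(barcodes)):
        raise ValueError("matrix dimensions do not match gene/barcode lists")
    mmwrite(str(dirpath / "matrix.mtx"), M, field="integer")
    (dirpath / "features.tsv").write_text("".join(f"{g}\n" for g in gene_ids))
    (dirpath / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))


def read_matrix_10x(dirpath) -> ad.AnnData:
    """Read a 10x-style triplet directory into AnnData (cells x genes).

    Rejects malformed dialects with explicit messages: dimension
    mismatches between the matrix header and the feature/barcode files,
    empty feature/barcode files, and coordinate entries that look 0-based
    (MatrixMarket indices are 1-based by definition).
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    with _open_maybe_gz(mtx_path) as fh:
        try:
            M = mmread(fh)
        except Exception as exc:  # includes negative indices after the 1-based shift
            raise ValueError(
                f"{mtx_path}: not a valid 1-based MatrixMarket coordinate file "
                f"({exc})"
            ) from exc
    M = sp.csr_matrix(M)

    with _open_maybe_gz(_find(dirpath, "features.tsv")) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(_find(dirpath, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"{dirpath}/features.tsv is empty")
    if not barcodes:
        raise ValueError(f"{dirpath}/barcodes.tsv is empty")
    if M.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {M.shape[0]} x {M.shape[1]} but found "
            f"{len(genes)} features and {len(barcodes)} barcodes"
        )
    adata = ad.AnnData(
        X=sp.csr_matrix(M.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = True) -> None:
    """CSV with ``#`` provenance header lines (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
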