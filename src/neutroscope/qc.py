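"""Per-cell quality control, normalization, and highly-variable-gene selection.

QC metrics and filters follow the conventional droplet workflow: cells are
removed when the number of detected gene features exceeds 2500 or falls
below 200, or when more than 10% of UMIs come from mitochondrial genes
(identifier prefix ``MT-``, case-insensitive). The thresholds describe
removal by strict inequality, so boundary values (exactly 200, 2500 or
10%) are kept.

Normalization is library-size scaling to a fixed total followed by
log1p: x -> ln(1 + scale * count / cell_total), with scale 1e4.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["compute_qc", "filter_cells", "normalize_log", "select_hvg"]

MITO_PATTERN = r"(?i)^MT-"


def _get_matrix_and_genes(counts):
    if hasattr(counts, "X"):
        return sp.csr_matrix(counts.X), list(counts.var_names), list(counts.obs_names)
    X = sp.csr_matrix(counts)
    return X, [str(i) for i in range(X.shape[1])], [str(i) for i in range(X.shape[0])]


def compute_qc(counts, mito_pattern: str = MITO_PATTERN) -> pd.DataFrame:
    """Per-cell QC metrics: n_features, total_umi, mito_pct.

    ``mito_pct`` is the percentage of UMIs from genes matching
    ``mito_pattern``; it is 0 by convention for cells with zero total UMIs
    or when no mitochondrial gene exists.
    """
    X, genes, barcodes = _get_matrix_and_genes(counts)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (X.data < 0).any():
        raise ValueError("count matrix must be non-negative")
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    pat = re.compile(mito_pattern)
    mito_mask = np.array([bool(pat.search(g)) for g in genes])
    if mito_mask.any():
        mito_umi = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_umi = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito_umi / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"n_features": n_features.astype(int), "total_umi": total.astype(int),
         "mito_pct": mito_pct},
        index=pd.Index(barcodes, name="barcode"),
    )


def filter_cells(metrics: pd.DataFrame, min_features: int = 200,
                 max_features: int = 2500, max_mito_pct: float = 10.0) -> np.ndarray:
    """Boolean keep-mask; removal by strict inequality, boundaries kept."""
    if min_features <= 0 or max_features <= 0 or min_features >= max_features:
        raise ValueError("thresholds must be positive with min_features < max_features")
    nf = metrics["n_features"].to_numpy()
    mito = metrics["mito_pct"].to_numpy()
    return (nf >= min_features) & (nf <= max_features) & (mito <= max_mito_pct)


def normalize_log(counts, scale: float = 1e4):
    """Library-size normalize and log1p-transform.

    Returns an object of the same kind as the input: an AnnData copy with
    the normalized matrix in ``.X`` (raw counts kept in
    ``.layers["counts"]``), or a sparse matrix for array-like input.
    Zero-total cells are an error naming the barcode.
    """
    X, genes, barcodes = _get_matrix_and_genes(counts)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = [barcodes[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total UMIs cannot be normalized: {bad}")
    norm = X.astype(np.float64).tocsr(copy=True)
    row_scale = scale / totals
    norm.data *= np.repeat(row_scale, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    if hasattr(counts, "X"):
        out = counts.copy()
        out.layers["counts"] = counts.X.copy()
        out.X = norm
        return out
    return norm


def select_hvg(normalized, n_top: int = 2000, n_bins: int = 20):
    """Rank genes by a variance-stabilized dispersion statistic.

    Statistic: residual of log variance (of normalized expression) against
    a running-median trend over mean-expression bins. Ties break by gene
    identifier (lexicographic), so the ranking is fully deterministic.
    Returns the ordered list of the top ``n_top`` gene identifiers.
    """
    X, genes, _ = _get_matrix_and_genes(normalized)
    if n_top > X.shape[1]:
        raise ValueError("n_top exceeds the number of genes")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean ** 2, 0.0)
    logvar = np.log1p(var)

    order = np.argsort(mean, kind="stable")
    trend = np.empty_like(logvar)
    edges = np.array_split(order, n_bins)
    for idx in edges:
        if len(idx):
            trend[idx] = np.median(logvar[idx])
    resid = logvar - trend
    # constant genes can never be variable, whatever their bin median
    resid[var == 0] = -np.inf
    key = sorted(range(len(genes)), key=lambda i: (-resid[i], genes[i]))
    return [genes[i] for i in key[:n_top]]
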