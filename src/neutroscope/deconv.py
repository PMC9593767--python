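"""Signature-based deconvolution of bulk expression into cell-type fractions.

A reference signature matrix is built from labeled single-cell data: the
union of the top marker genes per type (ranked by one-vs-rest log2 fold
change) by per-type mean linear-scale expression. Bulk samples are then
decomposed over the signature columns by non-negative least squares on
the shared genes, after bringing every column (bulk and signature) to a
common total, and the non-negative solution is renormalized to fractions
summing to one. This is the constrained-regression reading of
reference-profile deconvolution a la CIBERSORT; the nu-SVR variant of the
original is intentionally out of scope and NNLS is the reference solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from .clustering import find_markers

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "build_signature_matrix",
    "deconvolve",
    "evaluate_deconv",
]


@dataclass
class SignatureMatrix:
    profiles: pd.DataFrame  # marker genes x cell types, linear scale

    @property
    def genes(self):
        return list(self.profiles.index)

    @property
    def types(self):
        return list(self.profiles.columns)


@dataclass
class DeconvResult:
    fractions: pd.DataFrame  # samples x types, rows sum to 1
    residuals: pd.Series  # per-sample residual norm
    method: str = "nnls"


def build_signature_matrix(normalized, labels, markers_per_type: int = 50,
                           min_cells: int = 10,
                           marker_table: pd.DataFrame | None = None) -> SignatureMatrix:
    """Reference profile from labeled single-cell expression.

    ``normalized`` is log1p expression (AnnData or matrix); entries of the
    signature are per-type means of expm1(normalized). A precomputed
    marker table (from ``find_markers``) may be supplied, otherwise one is
    computed. Warns when the signature is ill-conditioned.
    """
    if hasattr(normalized, "X"):
        genes = list(normalized.var_names)
        X = normalized.X
    else:
        X = normalized
        genes = [str(i) for i in range(X.shape[1])]
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    low = [str(u) for u, c in zip(uniq, counts) if c < min_cells]
    if low:
        raise ValueError(f"types below the {min_cells}-cell floor: {low}")

    if marker_table is None:
        marker_table = find_markers(normalized, labels)
    chosen = []
    for u in uniq:
        sub = marker_table[marker_table["cluster"] == u]
        k = min(markers_per_type, len(sub))
        if k < markers_per_type:
            warnings.warn(f"type {u}: only {k} markers available")
        chosen += list(sub.nlargest(k, "log2fc")["gene"])
    marker_genes = sorted(set(chosen))
    gidx = {g: i for i, g in enumerate(genes)}
    rows = [gidx[g] for g in marker_genes]

    lin = np.expm1(X[:, rows])
    prof = np.stack([lin[labels == u].mean(axis=0) for u in uniq], axis=1)
    profiles = pd.DataFrame(prof, index=marker_genes, columns=[str(u) for u in uniq])
    cond = np.linalg.cond(profiles.to_numpy())
    if cond > 1e6:
        warnings.warn(f"signature matrix is ill-conditioned (cond={cond:.2g})")
    return SignatureMatrix(profiles=profiles)


def deconvolve(bulk: pd.DataFrame, signature: SignatureMatrix) -> DeconvResult:
    """Estimate cell-type fractions per bulk sample by NNLS.

    ``bulk`` is genes x samples on a linear scale (log-scale input, all
    values < 50, is expm1-reversed with a warning). At least half the
    signature genes must be present in the bulk index.
    """
    if (bulk.to_numpy() < 0).any():
        raise ValueError("bulk matrix must be non-negative")
    shared = [g for g in signature.genes if g in bulk.index]
    missing = [g for g in signature.genes if g not in bulk.index]
    if len(shared) < 0.5 * len(signature.genes):
        raise ValueError(
            f"only {len(shared)}/{len(signature.genes)} signature genes present; "
            f"missing e.g. {missing[:10]}"
        )
    B = bulk.loc[shared].to_numpy(dtype=float)
    if B.max() < 50:
        warnings.warn("bulk looks log-scale (max < 50); applying expm1")
        B = np.expm1(B)
    S = signature.profiles.loc[shared].to_numpy(dtype=float)

    # bulk columns are scaled to unit total (estimates are then invariant to
    # sequencing depth); the signature keeps its relative column scale — the
    # per-type mean expression levels — since rescaling columns individually
    # would be absorbed into the coefficients and bias the fractions. A
    # single global factor keeps the numerics of NNLS well-ranged.
    S = S / S.sum(axis=0).mean()
    col_tot = B.sum(axis=0, keepdims=True)
    col_tot[col_tot == 0] = 1.0
    B = B / col_tot

    fracs = np.zeros((B.shape[1], S.shape[1]))
    resid = np.zeros(B.shape[1])
    for j in range(B.shape[1]):
        f, r = nnls(S, B[:, j])
        total = f.sum()
        fracs[j] = f / total if total > 0 else np.full(len(f), 1.0 / len(f))
        resid[j] = r
    return DeconvResult(
        fractions=pd.DataFrame(fracs, index=bulk.columns, columns=signature.types),
        residuals=pd.Series(resid, index=bulk.columns, name="residual"),
    )


def evaluate_deconv(est: DeconvResult, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-type RMSE and Pearson r between estimated and true fractions.

    r is reported as NaN when either side is constant or when only one
    sample is available; the last row ``overall`` holds the means.
    """
    common_types = [t for t in est.fractions.columns if t in truth.columns]
    common_samples = [s for s in est.fractions.index if s in truth.index]
    if not common_types or not common_samples:
        raise ValueError("no overlapping samples/types between estimate and truth")
    E = est.fractions.loc[common_samples, common_types]
    T = truth.loc[common_samples, common_types]
    rows = []
    for t in common_types:
        e, tr = E[t].to_numpy(), T[t].to_numpy()
        rmse = float(np.sqrt(((e - tr) ** 2).mean()))
        if len(e) < 2 or np.all(e == e[0]) or np.all(tr == tr[0]):
            r = np.nan
        else:
            r = float(np.corrcoef(e, tr)[0, 1])
        rows.append((t, rmse, r))
    out = pd.DataFrame(rows, columns=["type", "rmse", "pearson_r"]).set_index("type")
    out.loc["overall"] = [out["rmse"].mean(), out["pearson_r"].mean()]
    return out
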