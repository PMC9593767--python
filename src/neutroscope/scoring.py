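"""Per-cell functional signature scores and mixture-model apoptosis calling.

Two scoring schemes are provided. ``score_mean`` averages the normalized
expression of a gene set — used for the apoptosis, maturation, azurophil
and interferon-response programs. ``score_weighted_z`` z-scores each gene
across all cells and averages weight * z with weights in {+1, -1} — the
aging-score construction, where a negative weight marks a gene whose
expression falls with the scored state.

The apoptotic classifier fits a two-component univariate Gaussian mixture
to the apoptosis score by expectation-maximization; the component with
the higher mean is designated apoptotic and each cell is assigned by
posterior probability (ties at 0.5 fall to the non-apoptotic side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

__all__ = [
    "SignatureSet",
    "GMMFit",
    "score_mean",
    "score_weighted_z",
    "fit_gmm_1d",
    "classify_apoptotic",
]


@dataclass
class SignatureSet:
    """Named gene set with optional per-gene weights (+1/-1)."""

    name: str
    genes: list
    weights: dict | None = None  # gene -> +1 / -1

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.weights is not None:
            bad = {g: w for g, w in self.weights.items() if w not in (1, -1)}
            if bad:
                raise ValueError(f"weights must be +1 or -1, got {bad}")
            missing = [g for g in self.genes if g not in self.weights]
            if missing:
                raise ValueError(f"genes without weights: {missing}")


def _expr(normalized):
    if hasattr(normalized, "X"):
        X = normalized.X
        genes = list(normalized.var_names)
    else:
        X = normalized
        genes = [str(i) for i in range(X.shape[1])]
    if sp.issparse(X):
        X = np.asarray(X.todense())
    return np.asarray(X, dtype=float), genes


def _present(signature: SignatureSet, genes: list) -> list:
    idx = {g: i for i, g in enumerate(genes)}
    present = [g for g in signature.genes if g in idx]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    absent = [g for g in signature.genes if g not in idx]
    if absent:
        warnings.warn(
            f"signature {signature.name!r}: dropping {len(absent)} absent gene(s)"
        )
    return present


def score_mean(normalized, signature: SignatureSet) -> np.ndarray:
    """Unweighted mean of normalized expression over present signature genes."""
    X, genes = _expr(normalized)
    idx = {g: i for i, g in enumerate(genes)}
    present = _present(signature, genes)
    return X[:, [idx[g] for g in present]].mean(axis=1)


def score_weighted_z(normalized, signature: SignatureSet) -> np.ndarray:
    """Per-cell mean of weight * z-score; constant genes are dropped."""
    if signature.weights is None:
        raise ValueError("score_weighted_z requires a weighted signature")
    X, genes = _expr(normalized)
    idx = {g: i for i, g in enumerate(genes)}
    present = _present(signature, genes)
    cols = X[:, [idx[g] for g in present]]
    sd = cols.std(axis=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all signature genes are constant across cells")
    cols = cols[:, usable]
    w = np.array([signature.weights[g] for g, u in zip(present, usable) if u],
                 dtype=float)
    z = (cols - cols.mean(axis=0)) / cols.std(axis=0)
    return (z * w).mean(axis=1)


@dataclass
class GMMFit:
    """Fitted two-component univariate Gaussian mixture.

    Components are canonicalized so component 0 has the lower mean. The
    log-likelihood trace is non-decreasing over EM iterations of the
    winning start.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    ll_trace: np.ndarray
    responsibilities: np.ndarray  # cells x 2, posterior of each component
    converged: bool
    n_iter: int
    values: np.ndarray = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "variance": self.variances, "weight": self.weights},
            index=["component_0_low", "component_1_high"],
        )


def _em(values, mu, var, w, tol, max_iter, var_floor):
    n = len(values)
    trace = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        log_pdf = norm.logpdf(values[:, None], loc=mu, scale=np.sqrt(var))
        log_w = np.log(w)
        joint = log_pdf + log_w
        mx = joint.max(axis=1, keepdims=True)
        lse = mx.ravel() + np.log(np.exp(joint - mx).sum(axis=1))
        ll = lse.sum()
        trace.append(ll)
        resp = np.exp(joint - lse[:, None])
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if ll - ll_prev < tol and it > 0:
            converged = True
            break
        ll_prev = ll
    return mu, var, w, np.array(trace), converged


def fit_gmm_1d(values, tol: float = 1e-8, max_iter: int = 500,
               n_init: int = 5, seed: int = 0) -> GMMFit:
    """EM fit of a two-component 1-D Gaussian mixture.

    The first start splits the data at the median (quantile
    initialization); the remaining ``n_init - 1`` starts draw random
    responsibilities. Variances are floored at 1e-6 * var(values) to
    prevent collapse; the best start by final log-likelihood wins.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)] if np.isnan(values).any() else values
    if len(values) < 10 or values.std() == 0:
        raise ValueError("need >= 10 finite values with positive spread")
    var_floor = 1e-6 * values.var()
    rng = np.random.default_rng(seed)

    best = None
    for init in range(n_init):
        if init == 0:
            med = np.median(values)
            lo, hi = values[values <= med], values[values > med]
            if len(hi) == 0:
                lo, hi = values[values < med], values[values >= med]
            mu = np.array([lo.mean(), hi.mean()])
            var = np.maximum(np.array([lo.var(), hi.var()]), var_floor)
            w = np.array([len(lo), len(hi)], dtype=float) / len(values)
        else:
            resp = rng.dirichlet([1.0, 1.0], size=len(values))
            nk = resp.sum(axis=0)
            mu = (resp * values[:, None]).sum(axis=0) / nk
            var = np.maximum(
                (resp * (values[:, None] - mu) ** 2).sum(axis=0) / nk, var_floor)
            w = nk / len(values)
        mu, var, w, trace, converged = _em(values, mu, var, w, tol, max_iter, var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (mu, var, w, trace, converged)

    mu, var, w, trace, converged = best
    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    log_pdf = norm.logpdf(values[:, None], loc=mu, scale=np.sqrt(var)) + np.log(w)
    mx = log_pdf.max(axis=1, keepdims=True)
    resp = np.exp(log_pdf - mx)
    resp /= resp.sum(axis=1, keepdims=True)
    return GMMFit(means=mu, variances=var, weights=w,
                  log_likelihood=float(trace[-1]), ll_trace=trace,
                  responsibilities=resp, converged=bool(converged),
                  n_iter=len(trace), values=values)


def classify_apoptotic(fit: GMMFit):
    """Assign each cell to the higher-mean (apoptotic) component.

    A cell is apoptotic when its posterior for the higher-mean component
    strictly exceeds 0.5; exact ties fall to the non-apoptotic side.
    Returns (boolean labels, apoptotic fraction).
    """
    post_high = fit.responsibilities[:, 1]
    labels = post_high > 0.5
    return labels, float(labels.mean())
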