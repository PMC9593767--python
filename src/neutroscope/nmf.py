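"""Non-negative matrix factorization with consensus rank selection.

Metagene modules within a cell subpopulation are found by factorizing the
(non-negative, log-normalized) genes x cells expression matrix V ~= W H
with multiplicative updates under the Frobenius objective. The number of
modules (the rank) is chosen by consensus clustering: the factorization
is repeated from many random starts, each cell is assigned to its
dominant metagene, and the stability of co-assignment across runs is
summarized by the cophenetic coefficient, dispersion, silhouette and the
best-run reconstruction error. The rank maximizing the cophenetic
coefficient wins (ties break by dispersion, then by smaller rank); the
full metric table stays available so the collective judgement is
auditable.

Per-cell module usage is the column-normalized H (sums to 1), aggregated
to per-sample means for severity association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "ModuleDecomposition",
    "RankMetricsTable",
    "nmf_factorize",
    "consensus_metrics",
    "select_rank",
    "module_usage",
    "aggregate_usage",
    "top_genes",
]

_EPS = 1e-12


@dataclass
class ModuleDecomposition:
    """NMF factors in canonical form (W columns sum to 1)."""

    W: np.ndarray  # genes x rank
    H: np.ndarray  # rank x cells
    rank: int
    rss: float  # squared Frobenius reconstruction error
    rss_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class RankMetricsTable:
    table: pd.DataFrame  # index rank; cophenetic, rss, dispersion, silhouette
    n_runs: int


def nmf_factorize(V, rank: int, seed: int = 0, max_iter: int = 1000,
                  tol: float = 1e-6) -> ModuleDecomposition:
    """Multiplicative-update NMF minimizing ||V - WH||_F^2.

    W and H start uniform-random; iteration stops when the relative change
    in the squared reconstruction error falls below ``tol``. On return W
    columns are scaled to unit L1 with the inverse scaling applied to H
    rows, leaving the product WH unchanged.
    """
    V = np.asarray(V, dtype=np.float64)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    n_genes, n_cells = V.shape
    if rank >= min(n_genes, n_cells):
        raise ValueError("rank must be smaller than both matrix dimensions")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.0, 1.0, size=(n_genes, rank)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(rank, n_cells)) * scale + _EPS

    trace = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        rss = float(((V - W @ H) ** 2).sum())
        trace.append(rss)
        if prev < np.inf and abs(prev - rss) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = rss
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    return ModuleDecomposition(W=W, H=H, rank=rank, rss=trace[-1],
                               rss_trace=np.array(trace), seed=seed,
                               n_iter=len(trace), converged=converged)


def consensus_metrics(V, ranks, n_runs: int = 30, seed: int = 0,
                      max_iter: int = 300, tol: float = 1e-5) -> RankMetricsTable:
    """Consensus stability metrics per candidate rank.

    For each rank, ``n_runs`` factorizations (seeds ``seed + run``) assign
    every cell to its argmax metagene; the consensus matrix C holds the
    fraction of runs co-assigning each cell pair. Reported per rank:

    - cophenetic: Pearson correlation between the condensed (1 - C)
      distances and the cophenetic distances of their average-linkage tree;
    - dispersion: mean of 4 (C - 1/2)^2 (1 for a binary consensus);
    - silhouette: mean silhouette of the consensus clustering (tree cut at
      the candidate rank) under distance 1 - C;
    - rss: best-run squared reconstruction error.
    """
    V = np.asarray(V, dtype=np.float64)
    n_cells = V.shape[1]
    ranks = [int(r) for r in ranks]
    if min(ranks) < 2:
        raise ValueError("ranks must be >= 2")
    if max(ranks) >= n_cells:
        raise ValueError("rank must be smaller than the number of cells")
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a consensus")

    records = []
    for rank in ranks:
        C = np.zeros((n_cells, n_cells))
        best_rss = np.inf
        for run in range(n_runs):
            fit = nmf_factorize(V, rank, seed=seed + run, max_iter=max_iter, tol=tol)
            best_rss = min(best_rss, fit.rss)
            assign = fit.H.argmax(axis=0)
            C += (assign[:, None] == assign[None, :])
        C /= n_runs
        np.fill_diagonal(C, 1.0)
        D = 1.0 - C
        condensed = squareform(D, checks=False)
        Z = average(condensed)
        if condensed.std() == 0:
            coph = 1.0  # ideal (binary, single-block) consensus
        else:
            coph = float(cophenet(Z, condensed)[0])
            if not np.isfinite(coph):
                coph = 1.0
        dispersion = float((4.0 * (C - 0.5) ** 2).mean())
        cut = fcluster(Z, t=rank, criterion="maxclust")
        if len(np.unique(cut)) < 2:
            sil = 0.0
        else:
            sil = float(silhouette_score(D, cut, metric="precomputed"))
        records.append((rank, coph, best_rss, dispersion, sil))
    table = pd.DataFrame(records, columns=["rank", "cophenetic", "rss",
                                           "dispersion", "silhouette"]).set_index("rank")
    return RankMetricsTable(table=table, n_runs=n_runs)


def select_rank(metrics: RankMetricsTable) -> int:
    """Rank maximizing the cophenetic coefficient.

    Ties break by higher dispersion, then by the smaller rank.
    """
    t = metrics.table
    if len(t) < 2:
        raise ValueError("need at least 2 candidate ranks")
    order = sorted(t.index, key=lambda r: (-t.loc[r, "cophenetic"],
                                           -t.loc[r, "dispersion"], r))
    return int(order[0])


def module_usage(H) -> np.ndarray:
    """Per-cell usage proportions: each H column divided by its sum."""
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    sums = H.sum(axis=0)
    if (sums == 0).any():
        bad = np.flatnonzero(sums == 0)[:5]
        raise ValueError(f"cells with all-zero usage: columns {bad.tolist()}")
    return (H / sums).T  # cells x modules


def aggregate_usage(usage, sample_ids) -> pd.DataFrame:
    """Per-sample mean module usage (samples x modules)."""
    usage = np.asarray(usage, dtype=float)
    sample_ids = np.asarray(sample_ids)
    if len(sample_ids) != usage.shape[0]:
        raise ValueError("sample_ids must match the number of cells")
    df = pd.DataFrame(usage, columns=[f"module_{i}" for i in range(usage.shape[1])])
    df["sample"] = sample_ids
    return df.groupby("sample", sort=False).mean()


def top_genes(W, gene_ids=None, n: int = 20) -> dict:
    """Per-module ranked gene lists by W weight (ties by gene id)."""
    W = np.asarray(W)
    if gene_ids is None:
        gene_ids = [str(i) for i in range(W.shape[0])]
    if n > W.shape[0]:
        raise ValueError("n exceeds the number of genes")
    out = {}
    for k in range(W.shape[1]):
        order = sorted(range(W.shape[0]), key=lambda i: (-W[i, k], gene_ids[i]))
        out[k] = [gene_ids[i] for i in order[:n]]
    return out
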