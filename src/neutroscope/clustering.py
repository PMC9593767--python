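"""Graph-based clustering with subsample stability analysis.

The clustering engine mirrors the two-step procedure used to subdivide
septic-blood neutrophils: Leiden community detection on a k-nearest-
neighbour graph built from the top principal components of the scaled
highly-variable-gene matrix, run across a grid of resolutions. Stability
at each resolution is measured by reclustering 90% subsamples (20
iterations, drawn without replacement) and computing the adjusted Rand
index (ARI) between the subsample solution and the full-data solution
restricted to the shared cells. The selected resolution is the highest
one before the mean ARI begins to decline.

Marker genes per cluster come from one-vs-rest Wilcoxon rank-sum tests
with Benjamini-Hochberg correction, log2 fold changes on expm1-means with
a pseudocount of 1, and expression-percentage filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import comb
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterLabels",
    "StabilityTable",
    "embed_pca",
    "cluster",
    "adjusted_rand_index",
    "stability_scan",
    "select_resolution",
    "find_markers",
]


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell integer label, contiguous from 0
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class StabilityTable:
    """Long table of (resolution, iteration, ari) plus per-resolution summary."""

    rows: pd.DataFrame
    summary: pd.DataFrame  # index resolution, columns mean_ari / sd_ari
    subsample_fraction: float
    n_iterations: int


def _to_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def embed_pca(matrix, n_pcs: int = 30, seed: int = 0, max_scaled: float = 10.0) -> np.ndarray:
    """Z-scale genes (clipped at ``max_scaled``) and project onto top PCs."""
    X = _to_dense(matrix)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -max_scaled, max_scaled)
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    return PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(Z)


def _knn_graph(embedding: np.ndarray, k: int) -> ig.Graph:
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    idx = nn.kneighbors(return_distance=False)  # self excluded
    src = np.repeat(np.arange(n), idx.shape[1])
    dst = idx.ravel()
    pairs = np.stack([np.minimum(src, dst), np.maximum(src, dst)], axis=1)
    pairs = np.unique(pairs, axis=0)
    return ig.Graph(n=n, edges=[tuple(e) for e in pairs], directed=False)


def cluster(data, resolution: float, seed: int = 0, *, k: int = 15,
            n_pcs: int = 30, is_embedding: bool | None = None) -> ClusterLabels:
    """Leiden clustering of cells at the given resolution.

    ``data`` is either a (cells x features) expression matrix — scaled and
    PCA-reduced internally — or an existing low-dimensional embedding
    (``is_embedding=True``, or inferred when the column count is at most
    ``n_pcs``). Deterministic for a fixed seed.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    X = _to_dense(data)
    if X.shape[0] < 50:
        raise ValueError("clustering requires at least 50 cells")
    if is_embedding is None:
        is_embedding = X.shape[1] <= n_pcs
    emb = X if is_embedding else embed_pca(X, n_pcs=n_pcs, seed=seed)
    graph = _knn_graph(emb, k)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    # contiguous relabel (leiden already emits 0..k-1, but guard anyway)
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterLabels(labels=labels, resolution=float(resolution), seed=int(seed))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2. When the denominator is
    zero (both partitions trivial) the index is 1 by convention.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = sp.coo_matrix(
        (np.ones(n), (ai, bi)),
        shape=(ai.max() + 1, bi.max() + 1),
    ).toarray()
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def stability_scan(data, resolutions, subsample_fraction: float = 0.9,
                   n_iterations: int = 20, seed: int = 0, *, k: int = 15,
                   n_pcs: int = 30, is_embedding: bool | None = None) -> StabilityTable:
    """Subsample/ARI stability of the clustering across resolutions.

    For each resolution the full data are clustered once (the reference);
    each iteration draws floor(fraction * n) cells without replacement
    (iteration i uses seed ``seed + i``), reclusters the subsample on the
    restricted embedding, and records the ARI between the subsample labels
    and the reference labels of the same cells.
    """
    resolutions = sorted(float(r) for r in resolutions)
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions to scan")
    if not 0.0 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1)")
    X = _to_dense(data)
    if is_embedding is None:
        is_embedding = X.shape[1] <= n_pcs
    emb = X if is_embedding else embed_pca(X, n_pcs=n_pcs, seed=seed)
    n = emb.shape[0]
    m = int(np.floor(subsample_fraction * n))
    if m <= k:
        raise ValueError("subsample smaller than the graph neighbourhood k")

    reference = {
        r: cluster(emb, r, seed=seed, k=k, is_embedding=True).labels
        for r in resolutions
    }
    records = []
    for it in range(n_iterations):
        it_seed = seed + it
        idx = np.random.default_rng(it_seed).choice(n, size=m, replace=False)
        sub_emb = emb[idx]
        sub_graph = _knn_graph(sub_emb, k)
        for r in resolutions:
            part = leidenalg.find_partition(
                sub_graph, leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=r, seed=int(it_seed), n_iterations=2,
            )
            ari = adjusted_rand_index(np.asarray(part.membership), reference[r][idx])
            records.append((r, it, ari))
    rows = pd.DataFrame(records, columns=["resolution", "iteration", "ari"])
    summary = rows.groupby("resolution")["ari"].agg(mean_ari="mean", sd_ari="std")
    return StabilityTable(rows=rows, summary=summary,
                          subsample_fraction=subsample_fraction,
                          n_iterations=n_iterations)


def select_resolution(table: StabilityTable, delta: float = 0.05) -> float:
    """Highest resolution before the mean ARI begins to decline.

    Returns r_k for the smallest k where mean ARI drops by more than
    ``delta`` from r_k to r_{k+1}; if the curve never drops that much, the
    largest scanned resolution is returned.
    """
    summary = table.summary.sort_index()
    res = summary.index.to_numpy()
    m = summary["mean_ari"].to_numpy()
    if len(res) == 1:
        warnings.warn("only one resolution scanned; returning it as-is")
        return float(res[0])
    for i in range(len(res) - 1):
        if m[i + 1] <= m[i] - delta:
            return float(res[i])
    return float(res[-1])


def find_markers(normalized, labels, min_log2fc: float = 0.25,
                 min_pct: float = 0.1) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per cluster.

    log2fc is computed on expm1-means with a pseudocount of 1; p-values
    are Benjamini-Hochberg adjusted across the whole table; rows failing
    ``min_log2fc`` or with both expression percentages below ``min_pct``
    are dropped. Columns: gene, cluster, log2fc, pct_in, pct_out, p, p_adj.
    """
    if hasattr(normalized, "X"):
        genes = list(normalized.var_names)
        X = _to_dense(normalized.X)
    else:
        X = _to_dense(normalized)
        genes = [str(i) for i in range(X.shape[1])]
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    small = [str(u) for u, c in zip(uniq, counts) if c < 3]
    if small:
        raise ValueError(f"clusters with fewer than 3 cells: {small}")

    lin = np.expm1(X)
    rows = []
    for u in uniq:
        mask = labels == u
        x_in, x_out = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided",
                                     method="auto")
        mean_in = lin[mask].mean(axis=0)
        mean_out = lin[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        pct_in = (x_in > 0).mean(axis=0)
        pct_out = (x_out > 0).mean(axis=0)
        df = pd.DataFrame({
            "gene": genes, "cluster": u, "log2fc": log2fc,
            "pct_in": pct_in, "pct_out": pct_out,
            "p": np.nan_to_num(res.pvalue, nan=1.0),
        })
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    keep = (table["log2fc"] >= min_log2fc) & (
        (table["pct_in"] >= min_pct) | (table["pct_out"] >= min_pct)
    )
    return (table[keep]
            .sort_values(["cluster", "log2fc"], ascending=[True, False])
            .reset_index(drop=True))
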