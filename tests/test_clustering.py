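"""ARI correctness, stability scan behaviour, resolution selection, markers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from neutroscope import (StabilityTable, adjusted_rand_index, cluster,
                         find_markers, select_resolution, stability_scan)


def brute_force_ari(a, b):
    """Pair-counting evaluation of the Hubert-Arabie formula, O(n^2)."""
    n = len(a)
    s11 = s_a = s_b = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        s11 += same_a and same_b
        s_a += same_a
        s_b += same_b
    pairs = n * (n - 1) / 2
    expected = s_a * s_b / pairs
    max_index = 0.5 * (s_a + s_b)
    if max_index == expected:
        return 1.0
    return (s11 - expected) / (max_index - expected)


def test_ari_known_values():
    assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
    assert np.isclose(adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]), -0.5)
    # degenerate: both partitions a single block
    assert adjusted_rand_index([0, 0, 0], [5, 5, 5]) == 1.0
    with pytest.raises(ValueError):
        adjusted_rand_index([1, 2], [1, 2, 3])


def test_ari_matches_bruteforce_and_sklearn(rng):
    for _ in range(200):
        n = int(rng.integers(3, 31))
        a = rng.integers(0, rng.integers(1, 6), n)
        b = rng.integers(0, rng.integers(1, 6), n)
        ours = adjusted_rand_index(a, b)
        assert abs(ours - brute_force_ari(a, b)) < 1e-12
        if len(np.unique(a)) > 1 or len(np.unique(b)) > 1:
            assert abs(ours - adjusted_rand_score(a, b)) < 1e-12


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 4), min_size=2, max_size=40),
       st.lists(st.integers(0, 4), min_size=2, max_size=40),
       st.permutations(range(5)))
def test_ari_symmetry_and_label_permutation(a, b, perm):
    n = min(len(a), len(b))
    a, b = np.array(a[:n]), np.array(b[:n])
    assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
    relabeled = np.array([perm[x] for x in a])
    assert adjusted_rand_index(a, b) == pytest.approx(
        adjusted_rand_index(relabeled, b))


def test_ari_permutation_null_is_centred(rng):
    vals = [adjusted_rand_index(rng.integers(0, 3, 1000), rng.integers(0, 3, 1000))
            for _ in range(100)]
    assert abs(np.mean(vals)) < 0.02


def _blobs(rng, centers, n_per, dim=10, sd=0.3):
    X = np.vstack([rng.normal(c, sd, size=(n_per, dim)) for c in centers])
    truth = np.repeat(np.arange(len(centers)), n_per)
    return X, truth


def test_cluster_separable_blobs_and_low_resolution_limit(rng):
    X, truth = _blobs(rng, [0.0, 5.0], 100)
    lab = cluster(X, resolution=0.5, seed=0, is_embedding=True)
    assert lab.n_clusters == 2
    assert adjusted_rand_index(lab.labels, truth) == 1.0
    # near-zero resolution on connected data collapses to one community
    connected = rng.normal(size=(200, 10))
    lab1 = cluster(connected, resolution=1e-4, seed=0, is_embedding=True)
    assert lab1.n_clusters == 1
    with pytest.raises(ValueError):
        cluster(X[:30], resolution=0.5, seed=0)
    with pytest.raises(ValueError):
        cluster(X, resolution=0.0, seed=0)


def test_stability_scan_sizes_and_separated_data(rng):
    X, truth = _blobs(rng, [0.0, 6.0, 12.0], 120)
    table = stability_scan(X, [0.1, 0.3], subsample_fraction=0.9,
                           n_iterations=4, seed=0, is_embedding=True)
    assert len(table.rows) == 8
    # floor convention: each subsample holds exactly floor(0.9 * 360) cells
    assert table.subsample_fraction == 0.9
    assert table.summary["mean_ari"].min() > 0.95
    # determinism
    t2 = stability_scan(X, [0.1, 0.3], subsample_fraction=0.9,
                        n_iterations=4, seed=0, is_embedding=True)
    pd.testing.assert_frame_equal(table.rows, t2.rows)


def test_select_resolution_decline_rule():
    def table(res, means):
        rows = pd.DataFrame({"resolution": res, "iteration": 0, "ari": means})
        summary = pd.DataFrame({"mean_ari": means, "sd_ari": 0.0},
                               index=pd.Index(res, name="resolution"))
        return StabilityTable(rows=rows, summary=summary,
                              subsample_fraction=0.9, n_iterations=1)

    t = table([0.05, 0.1, 0.15, 0.2, 0.3], [0.98, 0.97, 0.95, 0.70, 0.60])
    assert select_resolution(t, delta=0.05) == 0.15
    t2 = table([0.05, 0.1, 0.2], [0.5, 0.7, 0.9])
    assert select_resolution(t2) == 0.2
    with pytest.warns(UserWarning):
        assert select_resolution(table([0.1], [0.9])) == 0.1


def test_find_markers_separable_gene(rng):
    n = 120
    X = rng.poisson(1.0, size=(n, 30)).astype(float)
    labels = np.array([0] * 60 + [1] * 60)
    X[labels == 0, 0] += 5.0  # gene 0 expressed only/extra in cluster 0
    X[labels == 1, 0] = 0.0
    table = find_markers(np.log1p(X), labels)
    row = table[(table["gene"] == "0") & (table["cluster"] == 0)].iloc[0]
    assert row["pct_out"] < 0.05
    assert row["p_adj"] < 0.05
    with pytest.raises(ValueError):
        find_markers(np.log1p(X), np.zeros(n))


def test_find_markers_type_one_error_under_permutation(rng):
    n, g = 200, 2000
    X = np.log1p(rng.poisson(2.0, size=(n, g)).astype(float))
    labels = rng.permutation([0] * 100 + [1] * 100)
    table = find_markers(X, labels, min_log2fc=-np.inf, min_pct=0.0)
    frac = (table[table["cluster"] == 0]["p"] < 0.05).mean()
    assert abs(frac - 0.05) < 0.02


def test_find_markers_small_groups_match_exact_enumeration(rng):
    # tie-free small groups take the exact rank-sum path; verify against
    # full enumeration of the permutation distribution
    x = rng.normal(size=(12, 3))
    labels = np.array([0] * 6 + [1] * 6)
    table = find_markers(x - x.min() + 0.1, labels,
                         min_log2fc=-np.inf, min_pct=0.0)
    for j in range(3):
        col = x[:, j] - x.min() + 0.1
        obs_u = sum(1 for a in col[:6] for b in col[6:] if a > b)
        null = []
        for combo in itertools.combinations(range(12), 6):
            grp = np.zeros(12, bool)
            grp[list(combo)] = True
            null.append(sum(1 for a in col[grp] for b in col[~grp] if a > b))
        null = np.array(null)
        lo = min(obs_u, 36 - obs_u)
        p_exact = min(1.0, ((null <= lo).sum() + (null >= 36 - lo).sum()) / len(null))
        got = table[(table["gene"] == str(j)) & (table["cluster"] == 0)]["p"].iloc[0]
        assert got == pytest.approx(p_exact, abs=1e-12)


def test_planted_subtype_markers_recovered(small_atlas, small_normalized):
    _, adata, _, truth = small_atlas
    neu = (adata.obs["cell_type"] == "Neutrophil").to_numpy()
    nn = small_normalized[neu]
    sub = truth.neutrophil_subtype[neu].astype(str).to_numpy()
    table = find_markers(nn, sub)
    planted = {g for g, (t, _) in truth.marker_gene_assignment.items() if t == "Neu1"}
    top20 = table[table["cluster"] == "Neu1"].nlargest(20, "log2fc")["gene"]
    assert len(planted & set(top20)) >= len(planted) // 2
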