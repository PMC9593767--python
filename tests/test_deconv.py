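"""Signature construction and constrained-regression fraction recovery."""

import numpy as np
import pandas as pd
import pytest

from neutroscope import (DeconvResult, build_signature_matrix, deconvolve,
                         evaluate_deconv, simulate_pseudobulk)


@pytest.fixture(scope="module")
def labeled(small_atlas, small_normalized):
    _, adata, _, truth = small_atlas
    labels = np.where(adata.obs["cell_type"] == "Neutrophil",
                      adata.obs["neutrophil_subtype"].astype(str),
                      adata.obs["cell_type"])
    mt = pd.DataFrame(
        [(g, t, fc) for g, (t, fc) in truth.marker_gene_assignment.items()],
        columns=["gene", "cluster", "log2fc"])
    sig = build_signature_matrix(small_normalized, labels,
                                 markers_per_type=10, marker_table=mt)
    return adata, labels, sig, truth


def test_signature_shape_and_subtype_separation(labeled):
    _, labels, sig, _ = labeled
    assert set(sig.types) == set(np.unique(labels))
    assert (sig.profiles.to_numpy() >= 0).all()
    # planted subtype profiles must be distinguishable
    corr = sig.profiles.corr()
    for a in ("Neu1", "Neu2", "Neu3", "Neu4"):
        for b in ("Neu1", "Neu2", "Neu3", "Neu4"):
            if a != b:
                assert corr.loc[a, b] < 0.95


def test_signature_floor_and_marker_cap(small_normalized, small_atlas):
    _, adata, _, _ = small_atlas
    labels = np.array(["A"] * 5 + ["B"] * (adata.n_obs - 5))
    with pytest.raises(ValueError, match="floor"):
        build_signature_matrix(small_normalized, labels)


def test_exact_mixture_and_indicator_recovery(labeled, rng):
    _, _, sig, _ = labeled
    S = sig.profiles.to_numpy()
    f = rng.dirichlet(np.ones(S.shape[1]), size=6)
    bulk = pd.DataFrame(S @ f.T * 2e4, index=sig.genes,
                        columns=[f"M{i}" for i in range(6)])
    est = deconvolve(bulk, sig)
    assert np.abs(est.fractions.to_numpy() - f).max() < 1e-6
    # one pure signature column -> indicator fractions
    pure = pd.DataFrame(S[:, [2]] * 500.0, index=sig.genes, columns=["P"])
    est_pure = deconvolve(pure, sig)
    ind = np.zeros(S.shape[1])
    ind[2] = 1.0
    assert np.abs(est_pure.fractions.to_numpy()[0] - ind).max() < 1e-6


def test_scale_invariance_and_dummy_gene(labeled, rng):
    _, _, sig, _ = labeled
    S = sig.profiles.to_numpy()
    f = rng.dirichlet(np.ones(S.shape[1]))
    bulk = pd.DataFrame((S @ f)[:, None] * 1e4, index=sig.genes, columns=["s"])
    base = deconvolve(bulk, sig).fractions.to_numpy()
    scaled = deconvolve(bulk * 37.0, sig).fractions.to_numpy()
    assert np.abs(base - scaled).max() < 1e-9
    # an unexpressed gene added to both sides changes nothing
    sig2 = type(sig)(profiles=pd.concat(
        [sig.profiles, pd.DataFrame(0.0, index=["DUMMY"], columns=sig.types)]))
    bulk2 = pd.concat([bulk, pd.DataFrame(0.0, index=["DUMMY"], columns=["s"])])
    est2 = deconvolve(bulk2, sig2).fractions.to_numpy()
    assert np.abs(base - est2).max() < 1e-9


def test_noiseless_pseudobulk_recovery(labeled):
    adata, labels, sig, _ = labeled
    bulk, frac = simulate_pseudobulk(adata, labels,
                                     adata.obs["sample"].to_numpy(), noise_cv=0.0)
    est = deconvolve(bulk, sig)
    err = np.abs(est.fractions[frac.columns].to_numpy() - frac.to_numpy())
    # small fixture: library-size weighting noise dominates; bounded loosely
    assert err.max() < 0.08
    assert err.mean() < 0.02


def test_missing_gene_coverage_errors(labeled):
    _, _, sig, _ = labeled
    few = pd.DataFrame(1.0, index=sig.genes[: len(sig.genes) // 3],
                       columns=["s"])
    with pytest.raises(ValueError, match="signature genes"):
        deconvolve(few, sig)
    with pytest.raises(ValueError, match="non-negative"):
        deconvolve(pd.DataFrame(-1.0, index=sig.genes, columns=["s"]), sig)


def test_evaluate_deconv_identity_shuffle_and_degenerate(rng):
    truth = pd.DataFrame(rng.dirichlet(np.ones(3), size=12),
                         index=[f"s{i}" for i in range(12)],
                         columns=["A", "B", "C"])
    ident = DeconvResult(fractions=truth.copy(),
                         residuals=pd.Series(0.0, index=truth.index))
    ev = evaluate_deconv(ident, truth)
    assert (ev.loc[["A", "B", "C"], "rmse"] == 0).all()
    # row-shuffled estimates decorrelate from the truth
    rs = []
    for _ in range(50):
        shuffled = truth.sample(frac=1.0, random_state=rng.integers(1e6)).to_numpy()
        est = DeconvResult(fractions=pd.DataFrame(shuffled, index=truth.index,
                                                  columns=truth.columns),
                           residuals=pd.Series(0.0, index=truth.index))
        rs.append(evaluate_deconv(est, truth).loc["A", "pearson_r"])
    assert abs(np.nanmean(rs)) < 0.15
    # single sample: correlation undefined, RMSE still valid
    one = evaluate_deconv(
        DeconvResult(fractions=truth.iloc[:1],
                     residuals=pd.Series(0.0, index=truth.index[:1])),
        truth.iloc[:1])
    assert np.isnan(one.loc["A", "pearson_r"])
    assert one.loc["A", "rmse"] == 0.0
    # constant truth column guarded as missing
    const = truth.copy()
    const["A"] = 0.2
    ev_const = evaluate_deconv(ident, const)
    assert np.isnan(ev_const.loc["A", "pearson_r"])
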