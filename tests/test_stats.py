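"""Statistical layer: closed-form oracles, step-down correction, AUC, IRLS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neutroscope import (ShockModel, SimulationConfig, fit_logit_design,
                         holm_adjust, logistic_irls, pearson_test, roc_auc,
                         simulate_clinical_table, stratified_effect_curve,
                         student_test, welch_test)
from neutroscope.stats import build_interaction_design


def test_pearson_perfect_and_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_test(x, x).estimate == pytest.approx(1.0)
    assert pearson_test(x, -x).estimate == pytest.approx(-1.0)
    y = np.array([1.1, 1.9, 3.2, 3.8])
    res = pearson_test(x, y)
    # independent closed-form evaluation
    r = np.corrcoef(x, y)[0, 1]
    t = r * np.sqrt((len(x) - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), len(x) - 2)
    assert res.estimate == pytest.approx(r, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)
    with pytest.raises(ValueError):
        pearson_test([1, 1, 1], [1, 2, 3])
    # affine invariance up to sign
    res2 = pearson_test(3 * x + 7, y)
    assert res2.estimate == pytest.approx(res.estimate, abs=1e-12)


def test_t_tests_identity_and_welch_robustness(rng):
    x = np.array([1.0, 2.0, 3.0])
    res = welch_test(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert student_test(x, x).p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        welch_test([1.0], [1.0, 2.0])
    # variance ratio 16 with unbalanced n: Welch keeps level, Student drifts
    reps = 800
    pw, ps = [], []
    for _ in range(reps):
        a = rng.normal(0, 4, 10)
        b = rng.normal(0, 1, 100)
        pw.append(welch_test(a, b).p)
        ps.append(student_test(a, b).p)
    welch_rate = (np.array(pw) < 0.05).mean()
    student_rate = (np.array(ps) < 0.05).mean()
    assert abs(welch_rate - 0.05) < 0.03
    assert student_rate > welch_rate + 0.05


def test_holm_step_down():
    assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])
    assert holm_adjust([0.2]).tolist() == [0.2]
    assert np.allclose(holm_adjust([0.01, 0.01, 0.01]), [0.03, 0.03, 0.03])
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.2])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_holm_dominates_input(ps):
    adj = holm_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)


def test_auc_examples_and_antisymmetry(rng):
    assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    s = rng.normal(size=40)
    lab = rng.integers(0, 2, 40)
    if lab.min() == 0 and lab.max() == 1:
        assert roc_auc(s, lab) + roc_auc(-s, lab) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])
    # shuffled labels are uninformative on average
    vals = []
    for _ in range(200):
        perm = rng.permutation([0] * 15 + [1] * 15)
        vals.append(roc_auc(s[:30], perm))
    assert abs(np.mean(vals) - 0.5) < 0.02
    # bootstrap CI is seeded and ordered
    auc, (lo, hi) = roc_auc(s[:30], [0] * 15 + [1] * 15, n_boot=200, seed=3)
    assert lo <= auc + 0.25 and lo < hi


def test_logit_intercept_only_closed_form():
    y = np.array([1] * 30 + [0] * 70, dtype=float)
    fit = fit_logit_design(np.ones((100, 1)), y)
    assert fit.params.iloc[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)


def test_logit_matches_newton_raphson_oracle():
    cfg = SimulationConfig()
    clin = simulate_clinical_table(cfg, 200, seed=4)
    fit = logistic_irls(clin)
    X, names, _ = build_interaction_design(clin)
    y = clin["shock"].to_numpy(float)
    # independent Newton-Raphson oracle, written out explicitly
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        mu = 1 / (1 + np.exp(-X @ beta))
        W = mu * (1 - mu)
        beta = beta + np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (y - mu))
    assert np.abs(fit.params.to_numpy() - beta).max() < 1e-6
    # and statsmodels as a second independent implementation
    smf = sm.Logit(y, X).fit(disp=0)
    assert np.abs(fit.params.to_numpy() - smf.params).max() < 1e-6
    assert np.abs(fit.bse.to_numpy() - smf.bse).max() < 1e-6


def test_logit_recovers_planted_coefficients():
    cfg = SimulationConfig()  # planted (0.8, -0.5, -0.6)
    clin = simulate_clinical_table(cfg, 5000, seed=9)
    fit = logistic_irls(clin)
    b = cfg.shock_model
    for name, true in [("neu", b.beta_neu), ("mono", b.beta_mono),
                       ("neu_x_mono", b.beta_interaction)]:
        assert abs(fit.params[name] - true) < 2 * fit.bse[name]


def test_logit_guards():
    clin = simulate_clinical_table(SimulationConfig(), 60, seed=0)
    with pytest.raises(ValueError, match="rows"):
        logistic_irls(clin)
    sep = pd.DataFrame({
        "neutrophil_pct": np.r_[np.zeros(100), np.ones(100)],
        "monocyte_pct": np.random.default_rng(0).random(200),
        "age": 60.0, "sex": 0,
        "shock": np.r_[np.zeros(100), np.ones(100)],
    })
    with pytest.raises(RuntimeError):
        logistic_irls(sep)


def _results_with(params, mono_ref=(10.0, 2.0), neu_ref=(50.0, 8.0)):
    import neutroscope.stats as nst
    names = ["intercept", "neu", "mono", "neu_x_mono", "age", "sex"]
    return nst.LogitIRLSResults(
        params=pd.Series(params, index=names),
        bse=pd.Series(1.0, index=names), pvalues=pd.Series(1.0, index=names),
        fitted=np.array([]), n_iter=1, converged=True, llf=0.0,
        design_info={"neu": neu_ref, "mono": mono_ref},
    )


def test_stratified_curves_parallel_without_interaction():
    res = _results_with([0.0, 0.8, -0.5, 0.0, 0.0, 0.0])
    grid = np.linspace(30, 70, 5)
    curves = stratified_effect_curve(res, grid, mono_values=[6.0, 10.0, 14.0])
    assert ((curves["probability"] > 0) & (curves["probability"] < 1)).all()
    logit = np.log(curves["probability"] / (1 - curves["probability"]))
    wide = curves.assign(logit=logit).pivot(index="neutrophil",
                                            columns="monocyte", values="logit")
    diffs = wide.diff(axis=1).dropna(axis=1)
    assert np.allclose(diffs.std(axis=0), 0.0, atol=1e-10)


def test_stratified_curves_negative_interaction_flattens_slope():
    res = _results_with([0.0, 0.8, -0.5, -0.6, 0.0, 0.0])
    grid = np.linspace(30, 70, 9)
    curves = stratified_effect_curve(res, grid, mono_values=[6.0, 10.0, 14.0])
    slopes = []
    for mv, sub in curves.groupby("monocyte"):
        logit = np.log(sub["probability"] / (1 - sub["probability"]))
        slopes.append(np.polyfit(sub["neutrophil"], logit, 1)[0])
    assert slopes[0] > slopes[1] > slopes[2]
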