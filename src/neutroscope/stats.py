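"""Association statistics: correlation, two-sample tests, Holm correction,
ROC/AUC, and the interaction logistic model.

The logistic model follows the clinical analysis it supports: shock ~
neutrophil fraction + monocyte fraction + their interaction, adjusted for
age and sex, fitted by iteratively reweighted least squares with Wald
standard errors from the inverse information matrix. Covariates are
standardized (the interaction column is the product of the standardized
fractions) so main effects stay interpretable in the presence of the
product term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "pearson_test",
    "welch_test",
    "student_test",
    "holm_adjust",
    "roc_auc",
    "LogitIRLSResults",
    "build_interaction_design",
    "fit_logit_design",
    "logistic_irls",
    "stratified_effect_curve",
]


@dataclass
class StatResult:
    estimate: float
    statistic: float
    p: float
    method: str
    df: float | None = None
    two_sided: bool = True


def _check_pair(x, y, same_length=True):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if same_length and len(x) != len(y):
        raise ValueError("inputs must have equal length")
    return x, y


def pearson_test(x, y) -> StatResult:
    """Pearson correlation with the t-based two-sided p-value."""
    x, y = _check_pair(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    return StatResult(estimate=r, statistic=float(t), p=float(res.pvalue),
                      df=float(n - 2), method="pearson")


def _ttest(x, y, equal_var: bool, method: str) -> StatResult:
    x, y = _check_pair(x, y, same_length=False)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std() == 0 and y.std() == 0 and np.mean(x) == np.mean(y):
        return StatResult(estimate=0.0, statistic=0.0, p=1.0,
                          df=float(len(x) + len(y) - 2), method=method)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return StatResult(estimate=float(np.mean(x) - np.mean(y)),
                      statistic=float(res.statistic), p=float(res.pvalue),
                      df=float(res.df), method=method)


def welch_test(x, y) -> StatResult:
    """Welch two-sample t-test (Satterthwaite degrees of freedom)."""
    return _ttest(x, y, equal_var=False, method="welch")


def student_test(x, y) -> StatResult:
    """Student two-sample t-test with pooled variance."""
    return _ttest(x, y, equal_var=True, method="student")


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def roc_auc(scores, labels, n_boot: int = 0, seed: int = 0):
    """AUC as the Mann-Whitney U-statistic (ties get half credit).

    Returns the AUC, or (AUC, (lo, hi)) with a seeded percentile bootstrap
    CI when ``n_boot`` > 0.
    """
    scores, labels = _check_pair(scores, np.asarray(labels, dtype=float))
    labels = labels.astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def _auc(p, n):
        ranks = sps.rankdata(np.concatenate([p, n]))
        u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
        return u / (len(p) * len(n))

    auc = float(_auc(pos, neg))
    if n_boot <= 0:
        return auc
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        reps.append(_auc(bp, bn))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return auc, (float(lo), float(hi))


@dataclass
class LogitIRLSResults:
    """IRLS logistic fit: coefficients, Wald inference, predictions."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    n_iter: int
    converged: bool
    llf: float
    design_info: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "z": z, "p": self.pvalues})

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params.to_numpy()


def _standardize(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0), v.mean(), (sd if sd > 0 else 1.0)


def build_interaction_design(table: pd.DataFrame, neu_col: str = "neutrophil_pct",
                             mono_col: str = "monocyte_pct",
                             adjust=("age", "sex")) -> tuple[np.ndarray, list, dict]:
    """Design matrix for the shock interaction model.

    Continuous covariates are z-scored; the interaction column is the
    product of the standardized fractions; binary covariates (``sex``)
    enter as-is.
    """
    z_neu, m1, s1 = _standardize(table[neu_col])
    z_mono, m2, s2 = _standardize(table[mono_col])
    cols = [np.ones(len(table)), z_neu, z_mono, z_neu * z_mono]
    names = ["intercept", "neu", "mono", "neu_x_mono"]
    info = {"neu": (m1, s1), "mono": (m2, s2)}
    for a in adjust:
        v = table[a].to_numpy(dtype=float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            cols.append(v)
            info[a] = (0.0, 1.0)
        else:
            z, m, s = _standardize(v)
            cols.append(z)
            info[a] = (m, s)
        names.append(a)
    return np.column_stack(cols), names, info


def logistic_irls(table: pd.DataFrame, outcome: str = "shock",
                  neu_col: str = "neutrophil_pct", mono_col: str = "monocyte_pct",
                  adjust=("age", "sex"), tol: float = 1e-8,
                  max_iter: int = 100) -> LogitIRLSResults:
    """Fit the interaction logistic model by IRLS.

    Converges when the score (gradient) norm drops below ``tol``;
    non-convergence or detected separation raises rather than returning a
    silent result.
    """
    y = table[outcome].to_numpy(dtype=float)
    X, names, info = build_interaction_design(table, neu_col, mono_col, adjust)
    n, k = X.shape
    if n <= 10 * k:
        raise ValueError(f"need more than {10 * k} rows for {k} parameters")
    return fit_logit_design(X, y, names, design_info=info, tol=tol,
                            max_iter=max_iter)


def fit_logit_design(X, y, names=None, design_info=None, tol: float = 1e-8,
                     max_iter: int = 100) -> LogitIRLSResults:
    """IRLS logistic regression on an explicit design matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    beta = np.zeros(k)
    converged = False
    for it in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wvec = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        XtWX = X.T @ (X * wvec[:, None])
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix (separation?)") from exc
        beta = beta + step
        if np.abs(beta).max() > 50:
            raise RuntimeError("coefficients diverging; data may be separated")
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wvec = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * wvec[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    llf = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                       (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    return LogitIRLSResults(
        params=pd.Series(beta, index=names), bse=pd.Series(se, index=names),
        pvalues=pd.Series(p, index=names), fitted=mu, n_iter=it,
        converged=converged, llf=llf, design_info=design_info or {},
    )


def stratified_effect_curve(results: LogitIRLSResults, neu_grid,
                            mono_quantiles=(0.10, 0.50, 0.90),
                            mono_values=None, table: pd.DataFrame | None = None,
                            neu_col: str = "neutrophil_pct",
                            mono_col: str = "monocyte_pct") -> pd.DataFrame:
    """Predicted shock probability along a neutrophil grid per monocyte stratum.

    Monocyte strata default to the 10/50/90% quantiles of the fitting data
    (``table`` required unless explicit ``mono_values`` are given);
    adjustment covariates sit at their reference values (z = 0 /
    category 0). Warns when the grid leaves the observed range.
    """
    m_neu, s_neu = results.design_info["neu"]
    m_mono, s_mono = results.design_info["mono"]
    neu_grid = np.asarray(neu_grid, dtype=float)
    if table is not None:
        obs = table[neu_col].to_numpy(dtype=float)
        if neu_grid.min() < obs.min() or neu_grid.max() > obs.max():
            warnings.warn("neutrophil grid extends outside the observed range")
        if mono_values is None:
            mono_values = np.quantile(table[mono_col], mono_quantiles)
    if mono_values is None:
        raise ValueError("provide mono_values or the fitting table")

    b = results.params
    rows = []
    for mv in np.asarray(mono_values, dtype=float):
        z_m = (mv - m_mono) / s_mono
        z_n = (neu_grid - m_neu) / s_neu
        eta = (b["intercept"] + b["neu"] * z_n + b["mono"] * z_m
               + b["neu_x_mono"] * z_n * z_m)
        prob = 1.0 / (1.0 + np.exp(-eta))
        for g, pr in zip(neu_grid, prob):
            rows.append((mv, g, pr))
    return pd.DataFrame(rows, columns=["monocyte", "neutrophil", "probability"])
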