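"""Minimal diagnostic figures for the main result objects."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .clustering import StabilityTable  # noqa: E402
from .scoring import GMMFit  # noqa: E402


def plot_stability(table: StabilityTable, ax=None):
    """Mean +/- sd ARI across the scanned resolutions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    s = table.summary.sort_index()
    ax.errorbar(s.index, s["mean_ari"], yerr=s["sd_ari"].fillna(0.0),
                marker="o", capsize=3)
    ax.set_xlabel("resolution")
    ax.set_ylabel("adjusted Rand index")
    ax.set_ylim(-0.05, 1.05)
    return ax


def plot_gmm(fit: GMMFit, ax=None, bins: int = 60):
    """Score histogram with the two fitted Gaussian components."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.hist(fit.values, bins=bins, density=True, alpha=0.4, color="grey")
    grid = np.linspace(fit.values.min(), fit.values.max(), 400)
    from scipy.stats import norm
    for k, style in ((0, "C0"), (1, "C3")):
        ax.plot(grid, fit.weights[k] * norm.pdf(grid, fit.means[k],
                                                np.sqrt(fit.variances[k])),
                color=style,
                label=["non-apoptotic", "apoptotic"][k])
    ax.set_xlabel("score")
    ax.legend(frameon=False)
    return ax


def plot_effect_curves(curves, ax=None):
    """Predicted shock probability per monocyte stratum (from
    ``stratified_effect_curve``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for mv, sub in curves.groupby("monocyte"):
        ax.plot(sub["neutrophil"], sub["probability"],
                label=f"monocyte {mv:.1f}")
    ax.set_xlabel("neutrophil fraction")
    ax.set_ylabel("P(shock)")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax
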