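"""Minimal plotting helpers (requires matplotlib, an optional dependency)."""

from __future__ import annotations

import numpy as np

from .inference import PosteriorSample

__all__ = ["plot_chains", "plot_densities", "plot_prediction_band"]


def _plt():
    import matplotlib.pyplot as plt

    return plt


def plot_chains(sample: PosteriorSample, burn_in: int = 10000, thin: int = 50, axes=None):
    """Trace plots of the thinned post-burn-in chains, one panel per parameter."""
    plt = _plt()
    names = list(sample.param_names)
    if axes is None:
        _, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)), sharex=True)
    kept = sample.draws[burn_in::thin]
    it = np.arange(burn_in, len(sample.draws), thin)
    for ax, (j, name) in zip(np.atleast_1d(axes), enumerate(names)):
        ax.plot(it, kept[:, j], lw=0.5)
        ax.set_ylabel(name)
    return axes


def plot_densities(sample: PosteriorSample, burn_in: int = 10000, axes=None):
    """Posterior marginal densities with 2.5/50/97.5% quantile markers."""
    plt = _plt()
    names = list(sample.param_names)
    if axes is None:
        _, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3))
    kept = sample.draws[burn_in:]
    for ax, (j, name) in zip(np.atleast_1d(axes), enumerate(names)):
        ax.hist(kept[:, j], bins=60, density=True, alpha=0.7)
        for q, style in zip(np.quantile(kept[:, j], [0.025, 0.5, 0.975]),
                            ("--", "-", "--")):
            ax.axvline(q, color="k", ls=style, lw=1)
        ax.set_xlabel(name)
    return axes


def plot_prediction_band(table, ax=None):
    """Median and 95% band of predicted deaths per observation window."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    x = table["ytd"].to_numpy()
    ax.fill_between(x, table["q0.025"], table["q0.975"], alpha=0.3, label="95% band")
    ax.plot(x, table["q0.5"], marker="o", ms=3, label="median")
    if "measured" in table.columns:
        ax.plot(x, table["measured"], marker="x", ls="none", color="k", label="measured")
    ax.set_xlabel("observation window")
    ax.set_ylabel("deaths")
    ax.legend()
    return ax
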