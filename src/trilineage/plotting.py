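"""Minimal plotting helpers: the prior-odds sweep curve and the odds dot plot."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sweep_curve", "plot_odds_dotplot"]


def plot_sweep_curve(result, ax=None):
    """Posterior of each topology as a function of the prior odds."""
    import matplotlib.pyplot as plt

    if result.sweep is None:
        raise ValueError("result carries no sweep; run sweep_prior_odds")
    if ax is None:
        _fig, ax = plt.subplots()
    for t, name in enumerate(result.topology_names):
        ax.plot(result.odds_grid, result.sweep[:, t], label=f"root {name}" if t < 3 else name)
    ax.axhline(result.threshold, color="grey", ls=":", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("prior odds p(beta=1)/p(beta=0)")
    ax.set_ylabel("p(T | data)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_odds_dotplot(result, prior=None, ax=None):
    """Per-gene transition odds vs the cluster each gene votes most against."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    marg = result.marginals
    if marg is None or result.gene_odds is None:
        raise ValueError("result carries no marginals; run sweep_prior_odds")
    vote = np.argmax(marg.log_min, axis=1)
    odds = np.maximum(result.gene_odds, 1e-12)
    for row, label in enumerate(result.labels):
        sel = vote == row
        ax.plot(odds[sel], np.full(sel.sum(), row), "o", ms=4, alpha=0.6, label=label)
    ax.set_xscale("log")
    ax.set_yticks(range(3), [f"min in {l}" for l in result.labels])
    ax.set_xlabel("odds of being a transition gene")
    return ax
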