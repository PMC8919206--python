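"""Matplotlib views of stability results (bar charts, V-profile)."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    _, ax = plt.subplots(figsize=(8, 4))
    return ax


def plot_stability_bars(results, ax=None):
    """Grouped bars of per-method stability values, most stable gene first."""
    ax = _get_ax(ax)
    genes = results.ranking
    methods = [m for m in results.methods if m in results.stabilities]
    width = 0.8 / max(len(methods), 1)
    x = np.arange(len(genes))
    for i, m in enumerate(methods):
        vals = results.stabilities[m].reindex(genes)
        ax.bar(x + i * width, vals.to_numpy(), width, label=m)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(genes, rotation=45, ha="right")
    ax.set_ylabel("stability (lower = more stable)")
    ax.legend(fontsize="small")
    return ax


def plot_v_profile(profile, ax=None):
    """Bar chart of V(n, n+1) with the decision threshold line."""
    ax = _get_ax(ax)
    ns = sorted(profile.v_values)
    ax.bar([f"V{n}/{n+1}" for n in ns], [profile.v_values[n] for n in ns],
           color="steelblue")
    ax.axhline(profile.threshold, color="firebrick", ls="--",
               label=f"threshold {profile.threshold}")
    ax.set_ylabel("pairwise variation V")
    ax.legend(fontsize="small")
    return ax
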