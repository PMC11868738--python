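"""Figure output: observed-vs-simulated ANN distributions and GLMM effects."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ann import FEATURES

__all__ = ["plot_ann_distributions", "plot_glmm_effects"]

_FEATURE_TITLES = {"nests": "other nests", "leks": "leks", "edge": "meadow edge",
                   "shore": "shore"}


def plot_ann_distributions(results, path=None):
    """Grid of panels (feature rows x year columns): simulated ANN histogram
    in grey, observed ANN as a vertical line, pseudo p annotated."""
    years = sorted({y for (y, _) in results.tests}, key=str)
    fig, axes = plt.subplots(len(FEATURES), len(years),
                             figsize=(2.6 * len(years), 2.2 * len(FEATURES)),
                             squeeze=False)
    for i, feat in enumerate(FEATURES):
        for j, year in enumerate(years):
            ax = axes[i][j]
            t = results.tests[(year, feat)]
            ax.hist(t.simulated_anns, bins=30, color="0.7", density=True)
            ax.axvline(t.observed_ann, color="C3", lw=2)
            ax.set_title(f"{year} {_FEATURE_TITLES[feat]}\n$p_{{pseudo}}$={t.pseudo_p:.3g}",
                         fontsize=8)
            ax.set_yticks([])
            if i == len(FEATURES) - 1:
                ax.set_xlabel("ANN (m)", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_glmm_effects(results, path=None):
    """Forest plot of posterior means with 95% CrI for the model parameters."""
    tab = results.summary()
    names = list(tab.index)
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(names) + 1.5))
    ypos = np.arange(len(names))[::-1]
    ax.errorbar(tab["mean"], ypos,
                xerr=[tab["mean"] - tab["cri_2.5%"], tab["cri_97.5%"] - tab["mean"]],
                fmt="o", color="C0", capsize=3)
    ax.axvline(0, color="0.5", lw=1, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(names)
    ax.set_xlabel("posterior mean and 95% CrI (per-SD scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
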