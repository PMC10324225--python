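"""Small figure helpers (stacked context bars, effect-score heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .peaks import CONTEXTS


def plot_context_summary(summary: pd.DataFrame, path) -> None:
    """Stacked bars of context percentages, one bar per sign class."""
    fig, ax = plt.subplots(figsize=(4, 4))
    bottom = pd.Series(0.0, index=summary.index)
    for ctx in CONTEXTS:
        ax.bar(summary.index, summary[ctx], bottom=bottom, label=ctx)
        bottom += summary[ctx]
    ax.set_ylabel("% of peaks")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_effect_heatmap(ranking: pd.Series, effect: pd.DataFrame, path,
                        top_n: int = 15) -> None:
    """Two-panel figure: normalized |coefficients| above the per-cluster
    effect scores of the top-ranked TFs."""
    tfs = [t for t in ranking.index[:top_n] if t in effect.index]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(max(4, 0.5 * len(tfs)), 5),
        gridspec_kw={"height_ratios": [1, 2]}, sharex=False)
    ax0.bar(range(len(tfs)), ranking.loc[tfs])
    ax0.set_xticks(range(len(tfs)))
    ax0.set_xticklabels(tfs, rotation=90, fontsize=7)
    ax0.set_ylabel("|coef| (norm.)")
    sub = effect.loc[tfs]
    vmax = max(abs(sub.to_numpy()).max(), 1e-9)
    im = ax1.imshow(sub.T, aspect="auto", cmap="RdBu", vmin=-vmax, vmax=vmax)
    ax1.set_xticks(range(len(tfs)))
    ax1.set_xticklabels(tfs, rotation=90, fontsize=7)
    ax1.set_yticks(range(sub.shape[1]))
    ax1.set_yticklabels([f"cluster {c}" for c in sub.columns], fontsize=8)
    fig.colorbar(im, ax=ax1, label="effect score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
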