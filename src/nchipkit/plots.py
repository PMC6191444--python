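"""Figure helpers: meta-gene heatmap/profile, state-enrichment bars, Venn.

Thin matplotlib wrappers over the analysis results; every function
returns the Figure and optionally saves it.  Plotting clips -inf
enrichment sentinels at a configurable floor instead of dropping states.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metagene import MetageneMatrix
from .state_enrichment import StateEnrichmentResult

__all__ = ["metagene_heatmap", "metagene_profile", "state_enrichment_bars",
           "venn_bars"]


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def metagene_heatmap(m: MetageneMatrix, path=None, cmap="viridis"):
    """Genes x bins heatmap, rows grouped by cluster when labels exist."""
    order = (
        np.argsort(m.cluster_labels, kind="stable")
        if m.cluster_labels is not None
        else np.arange(len(m.genes))
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.values[order], aspect="auto", cmap=cmap,
                   interpolation="nearest")
    fb = m.flank_bins
    ax.axvline(fb - 0.5, color="w", lw=0.8)
    ax.axvline(fb + m.body_bins - 0.5, color="w", lw=0.8)
    ax.set_xticks([0, fb, fb + m.body_bins, m.n_columns - 1])
    ax.set_xticklabels([f"-{m.flank_bp//1000}kb", "TSS", "TES",
                        f"+{m.flank_bp//1000}kb"])
    ax.set_ylabel("genes")
    fig.colorbar(im, ax=ax, label="signal")
    return _finish(fig, path)


def metagene_profile(m: MetageneMatrix, path=None):
    """Mean profile per cluster (or one overall profile)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    fb = m.flank_bins
    x = np.arange(m.n_columns)
    if m.cluster_labels is None:
        ax.plot(x, m.values.mean(axis=0), label="all genes")
    else:
        for c in sorted(set(m.cluster_labels)):
            rows = m.values[m.cluster_labels == c]
            ax.plot(x, rows.mean(axis=0), label=f"cluster {c} (n={len(rows)})")
    for pos in (fb, fb + m.body_bins):
        ax.axvline(pos, color="k", lw=0.6, ls=":")
    ax.set_xticks([0, fb, fb + m.body_bins, m.n_columns - 1])
    ax.set_xticklabels([f"-{m.flank_bp//1000}kb", "TSS", "TES",
                        f"+{m.flank_bp//1000}kb"])
    ax.set_ylabel("mean signal")
    ax.legend(fontsize=8)
    return _finish(fig, path)


def state_enrichment_bars(res: StateEnrichmentResult, path=None,
                          floor: float = -6.0):
    """log2(observed/expected) per state; -inf sentinels clipped at floor."""
    t = res.table
    vals = np.clip(np.nan_to_num(t["log2_ratio"], neginf=floor), floor, None)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = ["tab:red" if v > 0 else "tab:blue" for v in vals]
    ax.bar(t["state"], vals, color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("log2 enrichment over genome")
    ax.tick_params(axis="x", rotation=45)
    return _finish(fig, path)


def venn_bars(counts: dict[str, int], path=None,
              labels: tuple[str, str] = ("A", "B")):
    """Proportional summary of shared / unique co-occupancy calls."""
    fig, ax = plt.subplots(figsize=(5, 3))
    keys = ["unique_A", "shared", "unique_B"]
    names = [f"unique {labels[0]}", "shared", f"unique {labels[1]}"]
    ax.bar(names, [counts.get(k, 0) for k in keys],
           color=["tab:green", "tab:gray", "tab:red"])
    ax.set_ylabel("peak calls")
    return _finish(fig, path)
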