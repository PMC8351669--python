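"""Static plot helpers: PCA, breakpoint histogram, dendrogram, module
heatmap, and upset-style intersection bars.  All functions return the
matplotlib Figure and optionally save it; none require a display."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pca_plot(scores, var_pct, color_by=None, label: str = "", path=None):
    """Scatter of samples on PC1/PC2 with explained-variance axis labels."""
    fig, ax = plt.subplots(figsize=(5, 4))
    c = None if color_by is None else np.asarray(color_by)
    sc = ax.scatter(scores[:, 0], scores[:, 1], c=c, cmap="viridis", s=30)
    if c is not None:
        fig.colorbar(sc, ax=ax, label=label)
    ax.set_xlabel(f"PC1 ({var_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({var_pct[1]:.1f}%)")
    return _finish(fig, path)


def breakpoint_histogram(summary, path=None):
    """Bar plot of pooled breakpoint counts over the age grid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if summary.histogram:
        ages = list(summary.histogram)
        ax.bar(ages, [summary.histogram[a] for a in ages], width=2.0)
        if summary.median_breakpoint is not None:
            ax.axvline(summary.median_breakpoint, ls="--", color="k",
                       label=f"median {summary.median_breakpoint:g}")
            ax.legend()
    ax.set_xlabel("breakpoint age (months)")
    ax.set_ylabel("breakpoints")
    return _finish(fig, path)


def module_dendrogram(tom, labels=None, path=None):
    """Average-linkage dendrogram of 1 - TOM (the module-detection tree)."""
    D = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    fig, ax = plt.subplots(figsize=(7, 3.5))
    hierarchy.dendrogram(Z, ax=ax, no_labels=True, color_threshold=0.0)
    ax.set_ylabel("1 - TOM")
    return _finish(fig, path)


def module_heatmap(expr_values, gene_ids, labels, module: str, eigengene=None,
                   path=None):
    """Z-scored expression of one module's genes, with its eigengene bar."""
    rows = [i for i, g in enumerate(gene_ids) if labels[g] == module]
    M = expr_values[rows, :]
    Z = (M - M.mean(axis=1, keepdims=True)) / np.where(
        M.std(axis=1, keepdims=True) > 0, M.std(axis=1, keepdims=True), 1.0
    )
    n_panels = 2 if eigengene is not None else 1
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(6, 4), sharex=True,
        gridspec_kw={"height_ratios": [3, 1]} if n_panels == 2 else None,
    )
    ax0 = axes[0] if n_panels == 2 else axes
    im = ax0.imshow(Z, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    fig.colorbar(im, ax=ax0, label="z-score")
    ax0.set_ylabel(f"{module} genes")
    if eigengene is not None:
        e = np.asarray(eigengene)
        axes[1].bar(np.arange(len(e)), e, color=np.where(e >= 0, "tab:red", "tab:blue"))
        axes[1].set_ylabel("ME")
    return _finish(fig, path)


def upset_bars(regions: dict, path=None, max_regions: int = 20):
    """Bar plot of exclusive intersection-region sizes (upset-style)."""
    items = sorted(regions.items(), key=lambda kv: -len(kv[1]))[:max_regions]
    names = ["+".join(sorted(k)) for k, _ in items]
    sizes = [len(v) for _, v in items]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(items)), 3.5))
    ax.bar(range(len(items)), sizes)
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("genes")
    return _finish(fig, path)
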