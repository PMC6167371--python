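"""Figure exports: PCA scatter, enrichment bars, z-score heatmap, KM curves.

All functions draw on a supplied or fresh matplotlib Axes and can write
straight to file; they are deliberately thin so the tables remain the
primary output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers never need a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["pca_scatter", "enrichment_barplot", "signature_heatmap", "km_plot"]

_SUBTYPE_COLORS = {"A": "#d62728", "B": "#1f77b4", "noncancer": "#7f7f7f"}


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def pca_scatter(
    coordinates: pd.DataFrame,
    labels: pd.Series,
    components: tuple[str, str] = ("PC1", "PC2"),
    path: str | Path | None = None,
    ax=None,
):
    """2-D scatter of a PC embedding colored by subtype/cluster label."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    labels = pd.Series(labels).reindex(coordinates.index)
    for lab in sorted(labels.unique()):
        mask = labels == lab
        ax.scatter(
            coordinates.loc[mask, components[0]],
            coordinates.loc[mask, components[1]],
            s=18,
            label=str(lab),
            color=_SUBTYPE_COLORS.get(lab),
            alpha=0.8,
        )
    ax.set_xlabel(components[0])
    ax.set_ylabel(components[1])
    ax.legend(frameon=False, fontsize=8)
    _finish(fig, path)
    return ax


def enrichment_barplot(table: pd.DataFrame, path: str | Path | None = None, ax=None):
    """Horizontal bars of -log2(q) for a (top-) enrichment table."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 0.4 * max(len(table), 2) + 1))
    else:
        fig = ax.figure
    vals = table["neg_log2_q"].iloc[::-1]
    ax.barh(np.arange(len(vals)), vals, color="#1f77b4")
    ax.set_yticks(np.arange(len(vals)))
    ax.set_yticklabels(vals.index, fontsize=8)
    ax.set_xlabel(r"$-\log_2(q)$")
    _finish(fig, path)
    return ax


def signature_heatmap(
    matrix: pd.DataFrame,
    sample_order: list[str] | None = None,
    path: str | Path | None = None,
    ax=None,
    cmap: str = "RdBu_r",
):
    """Genes x samples heatmap on a symmetric two-color scale."""
    if sample_order is not None:
        matrix = matrix[sample_order]
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    vmax = float(np.nanpercentile(np.abs(matrix.to_numpy()), 99)) or 1.0
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xlabel("samples")
    ax.set_ylabel("genes")
    fig.colorbar(im, ax=ax, shrink=0.7)
    _finish(fig, path)
    return ax


def km_plot(survival, path: str | Path | None = None, ax=None):
    """Step plot of per-group Kaplan-Meier curves from a SurvivalResult."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for lab, curve in survival.curves.items():
        ax.step(
            curve["time"], curve["survival"], where="post",
            label=str(lab), color=_SUBTYPE_COLORS.get(lab),
        )
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.legend(frameon=False, title=f"log-rank p = {survival.pvalue:.3g}", fontsize=8)
    _finish(fig, path)
    return ax
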