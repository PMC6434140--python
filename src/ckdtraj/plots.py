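"""Optional figures: stage-distribution heat maps, mean-vector fields and
SVM possibility heat maps.  All functions return the matplotlib Axes and
never call ``show()``; pass ``path`` to save."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .trajectory import ALL_STAGES

_G_LABELS = ["G1", "G2", "G3a", "G3b"]
_P_LABELS = ["(-)", "(+/-)", "(+)", "(2+)"]
_CAT_LABELS = ["Low", "Mod", "High", "Very"]


def _grid_axes(ax, xlabels, ylabels, xlabel, ylabel):
    ax.set_xticks(range(len(xlabels)), xlabels)
    ax.set_yticks(range(len(ylabels)), ylabels)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)


def plot_stage_grid(counts, path=None, ax=None, title=None):
    """4 x 4 stage-count heat map (rows G, columns proteinuria grade)."""
    counts = np.asarray(counts)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(counts, cmap="YlOrRd")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, f"{v:g}", ha="center", va="center", fontsize=9)
    _grid_axes(ax, _P_LABELS, _G_LABELS, "proteinuria grade", "GFR category")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, fraction=0.046)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_mean_vectors(mean_vectors, path=None, ax=None, scale=1.0):
    """Arrow field of per-stage mean change vectors on the stage grid.

    ``scale`` multiplies arrow length for legibility (the underlying
    vectors are reported unscaled elsewhere).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for stage in ALL_STAGES:
        g, p = stage.coord()
        v = mean_vectors.get(stage)
        if v is None:
            continue
        ax.annotate("", xy=(p + scale * v.dp, g + scale * v.dg),
                    xytext=(p, g),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.plot(p, g, "k.", ms=3)
    ax.set_xlim(-0.6, 3.6)
    ax.set_ylim(3.6, -0.6)
    _grid_axes(ax, _P_LABELS, _G_LABELS, "proteinuria grade", "GFR category")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_possibility_heatmap(grid, path=None, ax=None, title=None):
    """4 x 4 outcome-possibility heat map (baseline x comparison category)."""
    grid = np.asarray(grid)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, cmap="RdBu", vmin=0.0, vmax=1.0)
    for (i, j), v in np.ndenumerate(grid):
        ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    _grid_axes(ax, _CAT_LABELS, _CAT_LABELS,
               "category at comparison year", "category at baseline")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, fraction=0.046)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
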