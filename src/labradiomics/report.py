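"""Significance-grid heatmaps and run summaries.

Heatmaps show primary features (filters, 1-26) on the horizontal axis and
secondary features (statistics, 1-23) on the vertical axis.  Significant
cells are shaded by p-value bin (<0.001, <0.01, <0.025, <0.05); cells at or
above alpha, and missing cells, are left blank.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from . import volio
from .featstats import N_FILTERS, N_STATISTICS
from .inference import SignificanceGrid, grid_summary

P_BINS = (0.0, 0.001, 0.01, 0.025, 0.05)
_COLORS = ("#67000d", "#cb181d", "#fb6a4a", "#fcae91")


def plot_significance_grid(grid: SignificanceGrid, title: str, path) -> None:
    """One substructure's heatmap, blank where p >= alpha or missing."""
    cmap = ListedColormap(_COLORS)
    cmap.set_bad("white")
    norm = BoundaryNorm(P_BINS, cmap.N)
    with np.errstate(invalid="ignore"):
        shown = np.ma.masked_where(~(grid.p < grid.alpha), grid.p)
    fig, ax = plt.subplots(figsize=(7.5, 6))
    # transpose: filters horizontal, statistics vertical (statistic 1 on top)
    ax.imshow(shown.T, cmap=cmap, norm=norm, origin="upper", aspect="auto",
              extent=(0.5, N_FILTERS + 0.5, N_STATISTICS + 0.5, 0.5),
              interpolation="nearest")
    ax.set_xlabel("primary radiomic feature (filter index)")
    ax.set_ylabel("secondary radiomic feature (statistic index)")
    ax.set_xticks(range(1, N_FILTERS + 1, 2))
    ax.set_yticks(range(1, N_STATISTICS + 1, 2))
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pvalue_legend(path) -> None:
    """Stand-alone legend panel for the p-value bins."""
    fig, ax = plt.subplots(figsize=(3.2, 2.2))
    labels = [f"p < {hi}" for hi in P_BINS[1:]]
    for color, label in zip(_COLORS, labels):
        ax.bar(0, 0, color=color, label=label)
    ax.legend(loc="center", frameon=False, title="two-sided permutation p")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def grids_to_frame(grids: dict[int, SignificanceGrid]) -> pd.DataFrame:
    rows = []
    for label, grid in grids.items():
        fi, si = np.meshgrid(np.arange(1, N_FILTERS + 1), np.arange(1, N_STATISTICS + 1),
                             indexing="ij")
        rows.append(pd.DataFrame({
            "substructure": label,
            "filter_index": fi.ravel(),
            "statistic_index": si.ravel(),
            "p_value": grid.p.ravel(),
            "alpha": grid.alpha,
            "n_perm": grid.n_perm,
            "seed": grid.seed,
        }))
    return pd.concat(rows, ignore_index=True)


def grids_from_frame(df: pd.DataFrame) -> dict[int, SignificanceGrid]:
    out = {}
    for label, part in df.groupby("substructure"):
        p = np.full((N_FILTERS, N_STATISTICS), np.nan)
        p[part["filter_index"].to_numpy() - 1, part["statistic_index"].to_numpy() - 1] = \
            part["p_value"].to_numpy()
        out[int(label)] = SignificanceGrid(
            p, float(part["alpha"].iloc[0]), int(part["n_perm"].iloc[0]),
            int(part["seed"].iloc[0]), int(label))
    return out


def render_report(grids: dict[int, SignificanceGrid], out_dir, min_run: int = 3) -> dict:
    """Write per-substructure heatmaps, the legend panel, and a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for label, grid in sorted(grids.items()):
        name = volio.SUBSTRUCTURES[label]
        plot_significance_grid(grid, name.replace("_", " "), out / f"heatmap_{name}.png")
        summary[name] = grid_summary(grid, min_run)
    plot_pvalue_legend(out / "heatmap_pvalue_legend.png")
    return summary
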