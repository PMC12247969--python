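"""Optional plot outputs (matplotlib imported lazily)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stats import GroupComparison, weighted_histogram

__all__ = ["plot_thickness_histogram", "plot_group_violins", "plot_hist2d"]


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_thickness_histogram(thickness, areas, path: str | Path,
                             bins=None, label: str = "") -> None:
    """Triangle-area-weighted thickness histogram: the y-axis is the
    relative membrane *area* in each thickness bin, not triangle counts."""
    plt = _mpl()
    if bins is None:
        bins = np.arange(2.0, 6.01, 0.1)
    t = np.asarray(thickness, dtype=float)
    a = np.asarray(areas, dtype=float)
    ok = np.isfinite(t)
    mass, edges = weighted_histogram(t[ok], a[ok], bins)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.stairs(mass, edges, fill=True, alpha=0.6, label=label or None)
    ax.set_xlabel("thickness (nm)")
    ax.set_ylabel("relative membrane area")
    if label:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_violins(comparison: GroupComparison, path: str | Path) -> None:
    """Violin plot of per-surface median thicknesses per group."""
    plt = _mpl()
    labels = list(comparison.per_surface)
    data = [comparison.per_surface[k] for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 3.5))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.set_ylabel("per-surface median thickness (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_hist2d(counts, thickness_edges, log10c_edges, path: str | Path) -> None:
    """Per-patch mean thickness vs log10 curvedness as a 2D histogram."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    pc = ax.pcolormesh(thickness_edges, log10c_edges, np.asarray(counts).T,
                       cmap="viridis")
    fig.colorbar(pc, ax=ax, label="patches")
    ax.set_xlabel("mean thickness (nm)")
    ax.set_ylabel("log10 curvedness (1/nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
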