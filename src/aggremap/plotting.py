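"""Figure rendering: satellite hexbin maps and box/whisker plots.

Both functions write a PNG and return the matplotlib figure. Plots follow
the box/whisker convention used throughout: median, quartile box, 1.5×IQR
whiskers, individual points superimposed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .satellites import DensityMap  # noqa: E402


def plot_density_map(dmap: DensityMap, path: str | Path | None = None,
                     inner_radius_px: float = 13.0):
    """Render a seed-centred hexbin density map of satellite intensity."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(dmap.bin_values):
        ax.hexbin(dmap.bin_centers[:, 0], dmap.bin_centers[:, 1],
                  C=dmap.bin_values, gridsize=40, cmap="viridis",
                  reduce_C_function=np.sum)
    circ = plt.Circle((0, 0), inner_radius_px, fill=False, color="w", lw=1)
    ax.add_patch(circ)
    ax.set_xlabel("Δx (px)")
    ax.set_ylabel("Δy (px)")
    ax.set_title(f"inner region: {dmap.inner_percentage:.1f}% of intensity")
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_groups(groups: dict, path: str | Path | None = None,
                ylabel: str = "value"):
    """Box/whisker plot (median, quartiles, 1.5×IQR) with jittered points."""
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    ax.boxplot(data, labels=names, whis=1.5, showfliers=False)
    rng = np.random.default_rng(0)
    for i, v in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(v)), v,
                   s=8, alpha=0.5, color="k", zorder=3)
    ax.set_ylabel(ylabel)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
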