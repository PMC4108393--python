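"""Occupancy-abundance curve panels (one panel per survey-grid size)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_occupancy_curves(
    df: pd.DataFrame,
    hue: str = "month",
    out: str | None = None,
    title: str | None = None,
):
    """Plot mean occupancy vs pack density, one panel per grid size.

    ``df`` is a tidy results table with columns grid_km2, density,
    mean_occupancy, sd_occupancy and the ``hue`` column distinguishing the
    curves within a panel (month, hunting_units or loners).
    """
    grids = sorted(df["grid_km2"].unique())
    fig, axes = plt.subplots(
        2, 2, figsize=(9, 7), sharex=True, sharey=True, squeeze=False
    )
    for ax, area in zip(axes.ravel(), grids):
        sub = df[df["grid_km2"] == area]
        for level, grp in sub.groupby(hue):
            grp = grp.sort_values("density")
            ax.errorbar(
                grp["density"], grp["mean_occupancy"], yerr=grp["sd_occupancy"],
                marker="o", ms=3, capsize=2, label=f"{hue}={level}",
            )
        ax.set_title(f"{area:.0f} km$^2$ survey units")
        ax.set_ylim(-0.02, 1.05)
    for ax in axes[-1]:
        ax.set_xlabel("Wolf pack density (packs/1,000 km$^2$)")
    for ax in axes[:, 0]:
        ax.set_ylabel("Occupancy")
    axes[0, 0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
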