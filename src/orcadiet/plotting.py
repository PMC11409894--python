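"""Optional matplotlib figures for seasonal diet profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from orcadiet.diet_stats import SeasonalTrend


def plot_seasonal_trend(trend: SeasonalTrend, path: str | Path) -> None:
    """One panel per group: smoothed monthly proportion per species."""
    groups = sorted(trend.table["group"].unique())
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(7, 3 * len(groups)), squeeze=False, sharex=True
    )
    for ax, group in zip(axes[:, 0], groups):
        sub = trend.table[trend.table["group"] == group]
        for species, curve in sub.groupby("species"):
            c = curve.sort_values("month")
            ax.plot(c["month"], c["smoothed"], label=species, lw=1.5)
            ax.plot(c["month"], c["monthly_mean"], ".", ms=4, alpha=0.5)
        ax.set_ylabel("diet proportion")
        ax.set_title(f"{trend.group_by} = {group} (span {trend.span})")
        ax.set_ylim(0, 1)
    axes[-1, 0].set_xlabel("month")
    axes[0, 0].legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
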