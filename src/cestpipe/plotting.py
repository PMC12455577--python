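"""Optional mean +/- SEM bar plots of the statistics table.

Requires matplotlib (the ``plot`` extra); the rest of the package does
not import it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_group_bars"]


def plot_group_bars(
    stats_table: pd.DataFrame,
    pool: str,
    regions: list[str] | None = None,
    out_path: str | Path | None = None,
):
    """One panel per region: group mean +/- SEM bars for ``pool``, with
    '*'/'#' flags drawn over the flagged comparisons' treatment bars.
    Returns the matplotlib figure; saves to ``out_path`` if given
    (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = stats_table[stats_table["pool"] == pool]
    regions = regions or list(sub["region"])
    groups = sorted({c[len("mean_"):] for c in sub.columns if c.startswith("mean_")})
    fig, axes = plt.subplots(1, len(regions), figsize=(2.6 * len(regions), 3),
                             squeeze=False, sharey=True)
    for ax, region in zip(axes[0], regions):
        row = sub[sub["region"] == region].iloc[0]
        means = [row.get(f"mean_{g}", np.nan) for g in groups]
        sems = [row.get(f"sem_{g}", np.nan) for g in groups]
        x = np.arange(len(groups))
        ax.bar(x, means, yerr=sems, capsize=3, color="0.7", edgecolor="black")
        for i, g in enumerate(groups):
            flag = row.get(f"flag_{g}_vs_vehicle", "")
            if isinstance(flag, str) and flag:
                ax.text(i, means[i] + (sems[i] or 0) * 1.5, flag,
                        ha="center", fontsize=12)
        ax.set_xticks(x)
        ax.set_xticklabels(groups, rotation=45, ha="right", fontsize=8)
        ax.set_title(region, fontsize=9)
    axes[0][0].set_ylabel(f"{pool} AUC (ppm)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
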