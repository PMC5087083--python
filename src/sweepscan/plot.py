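"""Manhattan-style plots of the ZHp / ZFst window tracks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_COLORS = ("#4C72B0", "#9fb4d6")


def manhattan(
    stats: pd.DataFrame,
    z_column: str,
    out_path: str | Path,
    threshold: float | None = None,
    title: str | None = None,
) -> None:
    """One genome-wide scatter of a Z track with an optional threshold line.

    Chromosomes are laid end to end in input order and alternate colors;
    masked windows are skipped. Fatal if the column is missing or all-masked.
    """
    if z_column not in stats.columns:
        raise ValueError(f"column {z_column!r} not in the window table")
    usable = stats[stats[z_column].notna()]
    if len(usable) == 0:
        raise ValueError(f"no unmasked windows in track {z_column!r}")

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(usable.groupby("chrom", sort=False)):
        x = offset + (sub["start"] + sub["end"]) / 2
        ax.scatter(x, sub[z_column], s=4, color=_COLORS[i % 2], rasterized=True)
        ticks.append(float(x.mean()))
        labels.append(str(chrom))
        offset += int(stats.loc[stats["chrom"] == chrom, "end"].max())
    if threshold is not None:
        ax.axhline(threshold, color="crimson", linestyle="--", linewidth=1,
                   label=f"threshold {threshold}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(ticks, labels, fontsize=8)
    ax.set_ylabel(z_column)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150, metadata=_metadata(z_column, threshold))
    plt.close(fig)


def _metadata(z_column: str, threshold: float | None) -> dict[str, str]:
    # stash config in the image so runs are auditable
    return {"Title": f"{z_column} threshold={threshold}"}
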