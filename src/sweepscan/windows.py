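"""Sliding-window partition of chromosomes and SNP-to-window assignment.

Windows are 0-based half-open [start, end). A SNP at 1-based position p
(0-based p-1) belongs to every window with start <= p-1 < end. With the
default 50 kb windows stepping by 25 kb each SNP falls in up to two windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WindowSpec:
    window_size: int = 50_000
    step_size: int = 25_000
    min_snps_per_window: int = 10

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step_size >= 1):
            raise ValueError("require window_size >= step_size >= 1")
        if self.min_snps_per_window < 1:
            raise ValueError("min_snps_per_window must be >= 1")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a FASTA .fai index or a 2-column TSV.

    Both formats put the name in column 1 and the length in column 2; extra
    .fai columns are ignored.
    """
    lengths: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{i}: expected at least 2 columns")
        lengths[parts[0]] = int(parts[1])
    return lengths


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Tile each chromosome with sliding windows.

    Window starts are 0, step, 2*step, ...; a window is emitted iff its start
    is < the chromosome length, and the terminal window is truncated at the
    chromosome end. Returns a DataFrame (chrom, start, end) in input
    chromosome order.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, spec.step_size)
        ends = np.minimum(starts + spec.window_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def assign_snps(
    windows: pd.DataFrame,
    positions: pd.DataFrame,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Attach to each window the half-open index range of member SNPs.

    ``positions`` must hold the SNP table's chrom and 1-based pos columns in
    (chrom, pos) order; the returned copy of ``windows`` gains ``lo``/``hi``
    (row-index range into ``positions``) and ``n_snps``. Windows keep their
    members implicitly as the contiguous slice [lo, hi) — valid because both
    inputs are position-sorted. A SNP on a chromosome absent from
    ``chrom_lengths`` is fatal.
    """
    unknown = set(positions["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"SNPs on chromosomes missing from lengths: {sorted(unknown)}")

    win = windows.copy()
    lo = np.zeros(len(win), dtype=np.int64)
    hi = np.zeros(len(win), dtype=np.int64)
    pos_by_chrom = {
        chrom: (sub.index[0], sub["pos"].to_numpy())
        for chrom, sub in positions.groupby("chrom", sort=False)
    }
    for chrom, wsub in win.groupby("chrom", sort=False):
        if chrom not in pos_by_chrom:
            continue
        offset, pos = pos_by_chrom[chrom]
        pos0 = pos - 1  # 0-based
        lo[wsub.index] = offset + np.searchsorted(pos0, wsub["start"].to_numpy(), "left")
        hi[wsub.index] = offset + np.searchsorted(pos0, wsub["end"].to_numpy(), "left")
    win["lo"] = lo
    win["hi"] = hi
    win["n_snps"] = hi - lo
    return win
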