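#!/usr/bin/env python
"""Manhattan-style plots of the ZHp (per population) and ZFst tracks with the
default outlier thresholds. Writes results/plots/manhattan_*.png."""

from pathlib import Path

import pandas as pd

from sweepscan.plot import manhattan

SCAN = Path("results/scan")
OUT = Path("results/plots")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stats = pd.read_csv(SCAN / "window_stats.tsv", sep="\t")
    tracks = [c for c in stats.columns if c.startswith("z_hp_")] + ["z_fst"]
    for col in tracks:
        cut = -5.0 if col.startswith("z_hp_") else 4.5
        manhattan(stats, col, OUT / f"manhattan_{col}.png", threshold=cut, title=col)
        print(f"wrote {OUT}/manhattan_{col}.png")


if __name__ == "__main__":
    main()
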