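"""Outlier-window calling and merging into candidate sweep regions.

Three criteria, mirroring the standard empirical-outlier scan:

* ``zhp_threshold``   — windows with ZHp <= cut (default -5) in one population;
* ``zfst_threshold``  — windows with ZFst >= cut (default 4.5);
* ``joint_top_percent`` — windows simultaneously in the low ``percent``-tail of
  ZHp and the high ``percent``-tail of ZFst (default top 1%), i.e. low
  heterozygosity AND high differentiation.

Thresholds are inclusive at the boundary. Significant windows that overlap or
are bookended (end == next start) merge into one candidate region carrying the
most extreme member Z and the member count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REGION_COLUMNS = [
    "chrom", "start", "end", "criterion", "population", "peak_z", "n_windows",
]


@dataclass(frozen=True)
class OutlierCriterion:
    """Cut configuration for the three calling modes."""

    zhp_cut: float = -5.0
    zfst_cut: float = 4.5
    percent: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.percent < 100):
            raise ValueError("percent must be in (0, 100)")
        if self.zhp_cut >= 0:
            raise ValueError("zhp_cut must be negative")
        if self.zfst_cut <= 0:
            raise ValueError("zfst_cut must be positive")


def call_zhp_outliers(
    stats: pd.DataFrame, population: str, cut: float = -5.0
) -> pd.DataFrame:
    """Windows whose ZHp for ``population`` is <= cut (boundary inclusive)."""
    z = stats[f"z_hp_{population}"]
    return stats[z.notna() & (z <= cut)]


def call_zfst_outliers(stats: pd.DataFrame, cut: float = 4.5) -> pd.DataFrame:
    """Windows whose ZFst is >= cut (boundary inclusive)."""
    z = stats["z_fst"]
    return stats[z.notna() & (z >= cut)]


def call_joint_outliers(
    stats: pd.DataFrame, population: str, percent: float = 1.0
) -> pd.DataFrame:
    """Windows in the low ``percent`` tail of ZHp and the high tail of ZFst.

    Quantile cuts use linear interpolation over the sorted unmasked values of
    each track; both conditions are boundary-inclusive. With fewer than
    100/percent unmasked windows the quantiles are still computed (degenerate
    cuts fall on the extreme order statistics).
    """
    zhp = stats[f"z_hp_{population}"]
    zfst = stats["z_fst"]
    ok = zhp.notna() & zfst.notna()
    zhp_cut = np.quantile(zhp[ok], percent / 100.0)
    zfst_cut = np.quantile(zfst[ok], 1.0 - percent / 100.0)
    return stats[ok & (zhp <= zhp_cut) & (zfst >= zfst_cut)]


def merge_regions(
    significant: pd.DataFrame, criterion: str, population: str, z_column: str
) -> pd.DataFrame:
    """Merge overlapping/bookended significant windows into candidate regions.

    ``z_column`` names the track whose most extreme member value becomes
    ``peak_z`` (most negative for ZHp tracks, most positive for ZFst).
    Returns a DataFrame with REGION_COLUMNS, sorted by (chrom, start).
    """
    if len(significant) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    low_is_extreme = z_column.startswith("z_hp")
    rows = []
    sig = significant.sort_values(["chrom", "start"], kind="stable")
    for chrom, sub in sig.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        zs = sub[z_column].to_numpy()
        cur_start, cur_end = int(starts[0]), int(ends[0])
        cur_z, cur_n = float(zs[0]), 1
        for s, e, z in zip(starts[1:], ends[1:], zs[1:]):
            if s <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, int(e))
                cur_z = min(cur_z, float(z)) if low_is_extreme else max(cur_z, float(z))
                cur_n += 1
            else:
                rows.append((chrom, cur_start, cur_end, criterion, population, cur_z, cur_n))
                cur_start, cur_end, cur_z, cur_n = int(s), int(e), float(z), 1
        rows.append((chrom, cur_start, cur_end, criterion, population, cur_z, cur_n))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def call_regions(
    stats: pd.DataFrame,
    populations: tuple[str, str],
    criterion: OutlierCriterion | None = None,
) -> dict[str, pd.DataFrame]:
    """Run all three criteria and merge, keyed 'zhp_<pop>', 'zfst', 'joint_<pop>'."""
    crit = criterion or OutlierCriterion()
    out: dict[str, pd.DataFrame] = {}
    for pop in populations:
        sig = call_zhp_outliers(stats, pop, crit.zhp_cut)
        out[f"zhp_{pop}"] = merge_regions(sig, "zhp_threshold", pop, f"z_hp_{pop}")
    sig = call_zfst_outliers(stats, crit.zfst_cut)
    out["zfst"] = merge_regions(sig, "zfst_threshold", "both", "z_fst")
    for pop in populations:
        sig = call_joint_outliers(stats, pop, crit.percent)
        out[f"joint_{pop}"] = merge_regions(sig, "joint_top_percent", pop, f"z_hp_{pop}")
    return out


def regions_to_bed6(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6 view: name = criterion, score = |peak_z| scaled x100 capped at 1000."""
    if len(regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    bed = regions[["chrom", "start", "end"]].copy()
    bed["name"] = regions["criterion"] + ":" + regions["population"]
    bed["score"] = np.minimum((regions["peak_z"].abs() * 100).round().astype(int), 1000)
    bed["strand"] = "."
    return bed
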