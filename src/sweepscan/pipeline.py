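"""End-to-end scan: VCF -> allele counts -> windows -> ZHp/ZFst -> regions.

Pure functions of their inputs; the CLI and the analysis drivers are thin
wrappers over :func:`scan_vcf` and :func:`sweepscan.regions.call_regions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .regions import OutlierCriterion, call_regions
from .stats import window_statistics
from .variant_io import (
    AlleleCounts,
    FilterConfig,
    FilterCounters,
    PopulationMap,
    count_alleles,
    read_vcf,
)
from .windows import WindowSpec, assign_snps, make_windows


@dataclass
class ScanResult:
    stats: pd.DataFrame
    counts: AlleleCounts
    records: list
    counters: FilterCounters
    regions: dict[str, pd.DataFrame] = field(default_factory=dict)


def scan_vcf(
    vcf_path: str | Path,
    popmap: PopulationMap,
    chrom_lengths: dict[str, int],
    window_spec: WindowSpec | None = None,
    filters: FilterConfig | None = None,
    estimator: str = "hudson",
    criterion: OutlierCriterion | None = None,
) -> ScanResult:
    """Run the full sweep scan and call candidate regions."""
    window_spec = window_spec or WindowSpec()
    counters = FilterCounters()
    records = list(read_vcf(vcf_path, popmap, filters, counters))
    if not records:
        raise ValueError("no SNPs left after filtering; loosen the filters")
    counts = count_alleles(records, popmap)
    windows = make_windows(chrom_lengths, window_spec)
    assigned = assign_snps(windows, counts.df[["chrom", "pos"]], chrom_lengths)
    stats = window_statistics(assigned, counts, window_spec, estimator)
    regions = call_regions(stats, counts.populations, criterion)
    return ScanResult(
        stats=stats, counts=counts, records=records, counters=counters, regions=regions
    )
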