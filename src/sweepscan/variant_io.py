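"""Read multi-sample VCF, filter biallelic SNPs, and tally per-population allele counts.

The scan downstream needs two views of each SNP:

* REF/ALT-labelled allele counts per population (consistent labelling across
  populations, required by the Fst estimators), and
* within-population major/minor counts (the unpolarized inputs to pooled
  heterozygosity Hp).

Both are produced here from plain diploid GT calls; missing genotypes are
excluded from all counts, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


class VcfError(RuntimeError):
    """Fatal problem with a VCF input (missing sample, unsorted records, ...)."""


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of each sample to one of exactly two population labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        pops = sorted(set(self.assignments.values()))
        if len(pops) != 2:
            raise ValueError(
                f"expected exactly 2 populations, got {len(pops)}: {pops}"
            )

    @property
    def populations(self) -> tuple[str, str]:
        return tuple(sorted(set(self.assignments.values())))  # type: ignore[return-value]

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column TSV: sample_id <tab> population."""
        assignments: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{i}: sample {sample!r} listed twice")
            assignments[sample] = pop
        return cls(assignments)


@dataclass(frozen=True)
class FilterConfig:
    """SNP-level filters applied while streaming the VCF.

    min_call_rate: minimum fraction of non-missing genotypes (over all mapped
        samples) for a record to be kept; 0 disables.
    min_minor_count: minimum pooled minor-allele count (both populations
        combined) for a record to be kept; 0 disables.
    """

    min_call_rate: float = 0.0
    min_minor_count: int = 0


@dataclass
class SnpRecord:
    """One biallelic SNP with per-sample diploid calls.

    ``genotypes`` is an (n_samples, 2) int8 array of allele indices
    (0 = REF, 1 = ALT, -1 = missing), ordered as ``samples``.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotypes: np.ndarray


@dataclass
class FilterCounters:
    """Bookkeeping of records dropped while reading."""

    kept: int = 0
    multiallelic: int = 0
    non_snp: int = 0
    low_call_rate: int = 0
    low_minor_count: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_vcf(
    path: str | Path,
    popmap: PopulationMap,
    filters: FilterConfig | None = None,
    counters: FilterCounters | None = None,
) -> Iterator[SnpRecord]:
    """Stream filtered biallelic SnpRecords from a (plain or bgzipped) VCF.

    Samples in the output genotype arrays are ordered pop1-samples then
    pop2-samples (populations sorted lexically). Raises VcfError if a mapped
    sample is absent from the header or the VCF is unsorted within a
    chromosome. Non-SNP and multiallelic records are counted and skipped.
    """
    filters = filters or FilterConfig()
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    missing = [s for s in popmap.assignments if s not in header_samples]
    if missing:
        raise VcfError(f"samples in population map absent from VCF header: {missing}")

    pop1, pop2 = popmap.populations
    ordered = popmap.samples(pop1) + popmap.samples(pop2)
    col_idx = np.array([header_samples.index(s) for s in ordered])
    n = len(ordered)

    last: tuple[str, int] | None = None
    for var in vcf:
        if len(var.ALT) != 1:
            if counters is not None:
                counters.multiallelic += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            if counters is not None:
                counters.non_snp += 1
            continue
        if last is not None and var.CHROM == last[0] and var.POS < last[1]:
            raise VcfError(
                f"VCF not sorted: {var.CHROM}:{var.POS} after {last[0]}:{last[1]}"
            )
        last = (var.CHROM, var.POS)

        # genotype array: columns 0,1 are the two alleles, col 2 phasing
        gt = np.asarray(var.genotype.array(), dtype=np.int16)[col_idx, :2]
        gt = gt.astype(np.int8)
        gt[gt < 0] = -1

        called = (gt >= 0).all(axis=1)
        if filters.min_call_rate > 0 and called.sum() < filters.min_call_rate * n:
            if counters is not None:
                counters.low_call_rate += 1
            continue
        if filters.min_minor_count > 0:
            alt_count = int((gt[called] == 1).sum())
            total = int(2 * called.sum())
            if min(alt_count, total - alt_count) < filters.min_minor_count:
                if counters is not None:
                    counters.low_minor_count += 1
                continue
        if counters is not None:
            counters.kept += 1
        yield SnpRecord(var.CHROM, var.POS, ref, alt, gt)


@dataclass
class AlleleCounts:
    """Per-SNP, per-population allele counts in both labellings.

    ``df`` has one row per SNP: chrom, pos, ref, alt, then for each population
    label P: ``n_ref_P``, ``n_alt_P``, ``n_major_P``, ``n_minor_P``,
    ``major_P`` (the major allele's base; ties go to REF), and
    ``all_missing_P`` (flag: no called genotype in that population).
    """

    df: pd.DataFrame
    populations: tuple[str, str]
    pop_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_long_tsv(self, path: str | Path) -> None:
        """Write the long-format table: chrom pos pop major minor n_major n_minor."""
        rows = []
        for pop in self.populations:
            sub = self.df[["chrom", "pos", "ref", "alt"]].copy()
            sub["pop"] = pop
            sub["major"] = self.df[f"major_{pop}"]
            minor = np.where(
                self.df[f"major_{pop}"] == self.df["ref"], self.df["alt"], self.df["ref"]
            )
            sub["minor"] = minor
            sub["n_major"] = self.df[f"n_major_{pop}"]
            sub["n_minor"] = self.df[f"n_minor_{pop}"]
            rows.append(sub[["chrom", "pos", "pop", "major", "minor", "n_major", "n_minor"]])
        out = pd.concat(rows).sort_values(["chrom", "pos", "pop"], kind="stable")
        out.to_csv(path, sep="\t", index=False)


def count_alleles(
    records: Iterable[SnpRecord], popmap: PopulationMap
) -> AlleleCounts:
    """Tally REF/ALT and major/minor allele counts per SNP per population.

    The major allele is the one with the larger within-population count;
    ties resolve to REF so output is deterministic. Missing genotypes are
    excluded. A population with no called genotype at a SNP gets (0, 0)
    counts and an ``all_missing`` flag.
    """
    pop1, pop2 = popmap.populations
    n1 = len(popmap.samples(pop1))
    n2 = len(popmap.samples(pop2))

    cols: dict[str, list] = {k: [] for k in ("chrom", "pos", "ref", "alt")}
    refs1, alts1, refs2, alts2 = [], [], [], []
    for rec in records:
        g1 = rec.genotypes[:n1]
        g2 = rec.genotypes[n1 : n1 + n2]
        cols["chrom"].append(rec.chrom)
        cols["pos"].append(rec.pos)
        cols["ref"].append(rec.ref)
        cols["alt"].append(rec.alt)
        refs1.append(int((g1 == 0).sum()))
        alts1.append(int((g1 == 1).sum()))
        refs2.append(int((g2 == 0).sum()))
        alts2.append(int((g2 == 1).sum()))

    df = pd.DataFrame(cols)
    for pop, r, a in ((pop1, refs1, alts1), (pop2, refs2, alts2)):
        nr = np.asarray(r, dtype=np.int64)
        na = np.asarray(a, dtype=np.int64)
        df[f"n_ref_{pop}"] = nr
        df[f"n_alt_{pop}"] = na
        ref_major = nr >= na  # tie -> REF
        df[f"n_major_{pop}"] = np.where(ref_major, nr, na)
        df[f"n_minor_{pop}"] = np.where(ref_major, na, nr)
        df[f"major_{pop}"] = np.where(ref_major, df["ref"], df["alt"])
        df[f"all_missing_{pop}"] = (nr + na) == 0
    return AlleleCounts(df=df, populations=(pop1, pop2), pop_sizes={pop1: n1, pop2: n2})


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as 'transition' or 'transversion'.

    Transitions are the purine<->purine (A<->G) and pyrimidine<->pyrimidine
    (C<->T) exchanges; the other eight ordered pairs are transversions.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"alleles must be in ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


@dataclass
class VariantSummary:
    """Genome-wide variant bookkeeping per population."""

    n_snps: dict[str, int]            # segregating SNPs per population
    ts: int
    tv: int
    ts_tv: float | None               # None when tv == 0 (undefined, not inf)
    het_rate_per_kb: dict[str, float]  # heterozygous calls / individual / kb spanned


def summarize_variants(
    counts: AlleleCounts, records: Sequence[SnpRecord]
) -> VariantSummary:
    """Summarize SNP counts, ts/tv ratio, and per-population heterozygosity rate.

    The heterozygosity rate is defined here as the mean number of heterozygous
    genotype calls per individual per kilobase of spanned reference (from the
    first to the last SNP position, summed over chromosomes).
    """
    if len(counts) == 0:
        raise ValueError("empty allele-count table")
    pop1, pop2 = counts.populations
    df = counts.df

    n_snps = {
        pop: int(((df[f"n_minor_{pop}"] > 0)).sum()) for pop in (pop1, pop2)
    }
    ts = sum(
        1 for r, a in zip(df["ref"], df["alt"]) if (r, a) in TRANSITIONS
    )
    tv = len(df) - ts
    ts_tv = (ts / tv) if tv > 0 else None

    n1 = counts.pop_sizes[pop1]
    span = 0
    for _, sub in df.groupby("chrom", sort=False):
        span += int(sub["pos"].max() - sub["pos"].min() + 1)
    het = {pop1: 0, pop2: 0}
    for rec in records:
        g = rec.genotypes
        is_het = (g >= 0).all(axis=1) & (g[:, 0] != g[:, 1])
        het[pop1] += int(is_het[:n1].sum())
        het[pop2] += int(is_het[n1:].sum())
    kb = span / 1000.0
    het_rate = {
        pop: (het[pop] / counts.pop_sizes[pop] / kb) if kb > 0 else 0.0
        for pop in (pop1, pop2)
    }
    return VariantSummary(n_snps=n_snps, ts=ts, tv=tv, ts_tv=ts_tv, het_rate_per_kb=het_rate)
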