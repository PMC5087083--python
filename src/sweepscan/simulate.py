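"""Two-population diploid genotype simulator with planted selective sweeps.

The generator emulates the statistical structure a windowed ZHp/ZFst scan
assumes, without coalescent ancestry or linkage:

* each SNP draws an ancestral ALT frequency p ~ Uniform(0.05, 0.95);
* each population's frequency comes from the Balding–Nichols model,
  Beta(p(1-F)/F, (1-p)(1-F)/F), with F the background divergence;
* inside a planted sweep the target population's frequency is redrawn with
  F = f_sweep and then pushed toward the nearer of {0, 1} so the minor-allele
  frequency shrinks by the factor (1 - diversity_reduction) — a diversity
  reduction of 1 fixes the site in the swept population;
* genotypes are Binomial(2, p_pop) under Hardy–Weinberg; calls go missing
  independently at ``missing_rate``;
* sites are resampled until at least one REF and one ALT allele is observed
  across the union of both populations (a VCF record needs an observed ALT).

Sites are independent (no LD): the scan operates on per-window allele
frequencies, and independence keeps the test oracles exact. Everything is
reproducible from the seed; the emitted VCF is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SweepRegion:
    """A planted sweep: interval (0-based half-open), target population index
    (0 or 1), fraction of minor-allele frequency removed, and the divergence
    parameter used for the swept population's frequency draw."""

    chrom: str
    start: int
    end: int
    target_pop: int
    diversity_reduction: float = 0.95
    f_sweep: float = 0.6


@dataclass(frozen=True)
class SimConfig:
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    snp_density: float = 0.001       # SNPs per bp
    n_per_pop: int = 6               # diploids per population, as in the 6+6 study design
    f_background: float = 0.05
    sweep_regions: tuple[SweepRegion, ...] = ()
    missing_rate: float = 0.0
    ts_prob: float = 0.70            # P(substitution is a transition); ts/tv ~ 2.33
    pop_labels: tuple[str, str] = ("popA", "popB")
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.f_background, self.missing_rate, self.ts_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for sw in self.sweep_regions:
            if not (0 <= sw.start < sw.end <= self.chrom_length):
                raise ValueError(f"sweep {sw} outside chromosome")
            if not 0 <= sw.diversity_reduction <= 1:
                raise ValueError("diversity_reduction must lie in [0, 1]")
        spans: dict[str, list[tuple[int, int]]] = {}
        for sw in self.sweep_regions:
            for s, e in spans.get(sw.chrom, []):
                if sw.start < e and s < sw.end:
                    raise ValueError("sweep regions must not overlap")
            spans.setdefault(sw.chrom, []).append((sw.start, sw.end))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimResult:
    """In-memory simulation output; ``genotypes`` is (n_snps, 2*n_per_pop, 2)
    int8 with allele indices (-1 = missing), pop-1 samples first."""

    config: SimConfig
    sites: pd.DataFrame          # chrom, pos (1-based), ref, alt, in_sweep
    genotypes: np.ndarray
    truth: pd.DataFrame          # chrom, start, end, target_pop, diversity_reduction, f_sweep
    genes: pd.DataFrame          # chrom, start, end, gene_id

    @property
    def sample_names(self) -> list[str]:
        a, b = self.config.pop_labels
        n = self.config.n_per_pop
        return [f"{a}_{i + 1}" for i in range(n)] + [f"{b}_{i + 1}" for i in range(n)]

    def allele_counts(self) -> pd.DataFrame:
        """Internal REF/ALT tallies per population (round-trip oracle)."""
        n = self.config.n_per_pop
        g1, g2 = self.genotypes[:, :n], self.genotypes[:, n:]
        out = self.sites[["chrom", "pos", "ref", "alt"]].copy()
        for pop, g in zip(self.config.pop_labels, (g1, g2)):
            out[f"n_ref_{pop}"] = (g == 0).sum(axis=(1, 2))
            out[f"n_alt_{pop}"] = (g == 1).sum(axis=(1, 2))
        return out


def _balding_nichols(rng: np.random.Generator, p: float, f: float) -> float:
    if f <= 0:
        return p
    if f >= 1:
        return float(rng.random() < p)
    c = (1 - f) / f
    return float(rng.beta(p * c, (1 - p) * c))


def _sweep_for(config: SimConfig, chrom: str, pos0: int) -> SweepRegion | None:
    for sw in config.sweep_regions:
        if sw.chrom == chrom and sw.start <= pos0 < sw.end:
            return sw
    return None


def simulate(config: SimConfig) -> SimResult:
    """Run the generative model; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_pop
    snps_per_chrom = int(round(config.snp_density * config.chrom_length))
    if snps_per_chrom < 1:
        raise ValueError("snp_density too low: 0 SNPs per chromosome")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    in_sweep: list[bool] = []
    geno_rows: list[np.ndarray] = []

    for chrom in config.chrom_names:
        pos = np.sort(
            rng.choice(config.chrom_length, size=snps_per_chrom, replace=False)
        ) + 1  # 1-based
        for p1 in pos:
            sw = _sweep_for(config, chrom, int(p1) - 1)
            while True:
                anc = rng.uniform(0.05, 0.95)
                freqs = [
                    _balding_nichols(rng, anc, config.f_background) for _ in range(2)
                ]
                if sw is not None:
                    f_target = _balding_nichols(rng, anc, sw.f_sweep)
                    keep = 1.0 - sw.diversity_reduction
                    if f_target <= 0.5:
                        f_target *= keep
                    else:
                        f_target = 1.0 - (1.0 - f_target) * keep
                    freqs[sw.target_pop] = f_target
                g = np.empty((2 * n, 2), dtype=np.int8)
                for k, f in enumerate(freqs):
                    draws = rng.random((n, 2)) < f
                    g[k * n : (k + 1) * n] = draws.astype(np.int8)
                if config.missing_rate > 0:
                    miss = rng.random(2 * n) < config.missing_rate
                    g[miss] = -1
                observed = g[g >= 0]
                if observed.size and observed.min() == 0 and observed.max() == 1:
                    break
            ref_i = int(rng.integers(4))
            ref = _BASES[ref_i]
            if rng.random() < config.ts_prob:
                alt = _TRANSITION_OF[ref]
            else:
                alt = str(rng.choice([b for b in _BASES if b not in (ref, _TRANSITION_OF[ref])]))
            chroms.append(chrom)
            poss.append(int(p1))
            refs.append(str(ref))
            alts.append(alt)
            in_sweep.append(sw is not None)
            geno_rows.append(g)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "in_sweep": in_sweep}
    )
    truth = pd.DataFrame(
        [
            (sw.chrom, sw.start, sw.end, config.pop_labels[sw.target_pop],
             sw.diversity_reduction, sw.f_sweep)
            for sw in config.sweep_regions
        ],
        columns=["chrom", "start", "end", "target_pop", "diversity_reduction", "f_sweep"],
    )
    genes = _simulate_genes(rng, config)
    return SimResult(
        config=config,
        sites=sites,
        genotypes=np.stack(geno_rows),
        truth=truth,
        genes=genes,
    )


def _simulate_genes(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals, ~1 gene / 100 kb, 2–40 kb long."""
    rows = []
    gid = 0
    for chrom in config.chrom_names:
        cursor = int(rng.integers(1_000, 50_000))
        while cursor < config.chrom_length - 2_000:
            length = int(rng.integers(2_000, 40_000))
            end = min(cursor + length, config.chrom_length)
            gid += 1
            rows.append((chrom, cursor, end, f"gene{gid:05d}"))
            cursor = end + int(rng.integers(20_000, 150_000))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_vcf(result: SimResult, path: str | Path) -> None:
    """Serialize to a sorted, GT-only VCF 4.2 (plain text, byte-deterministic)."""
    config = result.config
    lines = ["##fileformat=VCFv4.2", "##source=sweepscan-simulator"]
    for chrom in config.chrom_names:
        lines.append(f"##contig=<ID={chrom},length={config.chrom_length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(result.sample_names)
    )
    gt_str = {(-1, -1): "./.", (0, 0): "0/0", (0, 1): "0/1", (1, 0): "0/1", (1, 1): "1/1"}
    for i, row in enumerate(result.sites.itertuples()):
        calls = "\t".join(
            gt_str[(int(a), int(b))] for a, b in result.genotypes[i]
        )
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_popmap(result: SimResult, path: str | Path) -> None:
    a, b = result.config.pop_labels
    n = result.config.n_per_pop
    lines = [f"{s}\t{a if i < n else b}" for i, s in enumerate(result.sample_names)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_bed(result: SimResult, path: str | Path) -> None:
    """Planted sweeps as BED: chrom start end target_pop dr f_sweep."""
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.target_pop}\t{r.diversity_reduction}\t{r.f_sweep}"
        for r in result.truth.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_genes_bed(result: SimResult, path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}"
        for r in result.genes.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_chrom_lengths(result: SimResult, path: str | Path) -> None:
    lines = [f"{c}\t{result.config.chrom_length}" for c in result.config.chrom_names]
    Path(path).write_text("\n".join(lines) + "\n")


def default_sweep_config(
    seed: int = 0,
    n_chrom: int = 5,
    chrom_length: int = 10_000_000,
    snp_density: float = 0.001,
    n_sweeps: int = 10,
    sweep_length: int = 100_000,
    diversity_reduction: float = 0.95,
    f_sweep: float = 0.6,
    **kwargs,
) -> SimConfig:
    """Study-scale scenario: n_sweeps planted sweeps spread evenly over the
    genome, alternating target population, away from chromosome ends."""
    sweeps = []
    per_chrom = [n_sweeps // n_chrom + (1 if i < n_sweeps % n_chrom else 0) for i in range(n_chrom)]
    k = 0
    for ci, count in enumerate(per_chrom):
        for j in range(count):
            start = int((j + 1) * chrom_length / (count + 1))
            start -= start % 25_000  # align to the default step
            sweeps.append(
                SweepRegion(
                    chrom=f"chr{ci + 1}",
                    start=start,
                    end=start + sweep_length,
                    target_pop=k % 2,
                    diversity_reduction=diversity_reduction,
                    f_sweep=f_sweep,
                )
            )
            k += 1
    return SimConfig(
        n_chrom=n_chrom,
        chrom_length=chrom_length,
        snp_density=snp_density,
        sweep_regions=tuple(sweeps),
        seed=seed,
        **kwargs,
    )
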