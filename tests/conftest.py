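import numpy as np
import pandas as pd
import pytest

from sweepscan.simulate import (
    SimConfig,
    SweepRegion,
    simulate,
    write_chrom_lengths,
    write_popmap,
    write_vcf,
)
from sweepscan.variant_io import PopulationMap


@pytest.fixture(scope="session")
def small_sim():
    """Small neutral 2-population simulation: 1 chromosome, ~200 SNPs, 6+6."""
    config = SimConfig(
        n_chrom=1, chrom_length=200_000, snp_density=0.001,
        f_background=0.05, missing_rate=0.05, seed=11,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def sweep_sim():
    """Simulation with one strong planted sweep per population."""
    config = SimConfig(
        n_chrom=2, chrom_length=1_000_000, snp_density=0.001, f_background=0.05,
        sweep_regions=(
            SweepRegion("chr1", 400_000, 500_000, target_pop=0,
                        diversity_reduction=0.95, f_sweep=0.6),
            SweepRegion("chr2", 600_000, 700_000, target_pop=1,
                        diversity_reduction=0.95, f_sweep=0.6),
        ),
        seed=7,
    )
    return simulate(config)


@pytest.fixture()
def sim_files(tmp_path, small_sim):
    """The small simulation serialized to disk: vcf, popmap, lengths paths."""
    paths = {
        "vcf": tmp_path / "sim.vcf",
        "popmap": tmp_path / "popmap.tsv",
        "lengths": tmp_path / "lengths.tsv",
    }
    write_vcf(small_sim, paths["vcf"])
    write_popmap(small_sim, paths["popmap"])
    write_chrom_lengths(small_sim, paths["lengths"])
    return paths


@pytest.fixture(scope="session")
def popmap_ab():
    return PopulationMap(
        {f"popA_{i+1}": "popA" for i in range(6)}
        | {f"popB_{i+1}": "popB" for i in range(6)}
    )


def write_minimal_vcf(path, records, samples=("s1", "s2")):
    """Hand-rolled VCF writer for edge-case fixtures.

    ``records`` are (chrom, pos, ref, alt, [gt strings]) tuples.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000000>",
        "##contig=<ID=chr2,length=1000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
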