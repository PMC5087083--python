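"""VCF reading, filtering, allele counting, and variant summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sweepscan.variant_io import (
    FilterConfig,
    FilterCounters,
    PopulationMap,
    SnpRecord,
    VcfError,
    classify_substitution,
    count_alleles,
    read_vcf,
    summarize_variants,
)

from conftest import write_minimal_vcf

TWO_POP = PopulationMap({"s1": "A", "s2": "B"})


class TestPopulationMap:
    def test_requires_exactly_two_populations(self):
        with pytest.raises(ValueError, match="2 populations"):
            PopulationMap({"s1": "A"})
        with pytest.raises(ValueError, match="2 populations"):
            PopulationMap({"s1": "A", "s2": "B", "s3": "C"})

    def test_from_tsv_rejects_duplicate_sample(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("s1\tA\ns1\tB\ns2\tB\n")
        with pytest.raises(ValueError, match="listed twice"):
            PopulationMap.from_tsv(p)


class TestReadVcf:
    def test_het_site_passes_through(self, tmp_path):
        vcf = write_minimal_vcf(
            tmp_path / "a.vcf", [("chr1", 10, "A", "G", ["0/1", "0/1"])]
        )
        recs = list(read_vcf(vcf, TWO_POP))
        assert len(recs) == 1
        assert recs[0].pos == 10 and recs[0].ref == "A" and recs[0].alt == "G"
        assert recs[0].genotypes.tolist() == [[0, 1], [0, 1]]

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        vcf = write_minimal_vcf(
            tmp_path / "a.vcf",
            [("chr1", 10, "C", "A,T", ["0/1", "0/2"]),
             ("chr1", 20, "C", "T", ["0/0", "1/1"])],
        )
        counters = FilterCounters()
        recs = list(read_vcf(vcf, TWO_POP, counters=counters))
        assert [r.pos for r in recs] == [20]
        assert counters.multiallelic == 1 and counters.kept == 1

    def test_indel_skipped(self, tmp_path):
        vcf = write_minimal_vcf(
            tmp_path / "a.vcf", [("chr1", 10, "AT", "A", ["0/1", "0/1"])]
        )
        counters = FilterCounters()
        assert list(read_vcf(vcf, TWO_POP, counters=counters)) == []
        assert counters.non_snp == 1

    def test_missing_sample_is_fatal_and_named(self, tmp_path):
        vcf = write_minimal_vcf(
            tmp_path / "a.vcf", [("chr1", 10, "A", "G", ["0/1", "0/1"])]
        )
        bad = PopulationMap({"s1": "A", "ghost": "B"})
        with pytest.raises(VcfError, match="ghost"):
            list(read_vcf(vcf, bad))

    def test_unsorted_vcf_is_fatal(self, tmp_path):
        vcf = write_minimal_vcf(
            tmp_path / "a.vcf",
            [("chr1", 20, "A", "G", ["0/1", "0/1"]),
             ("chr1", 10, "C", "T", ["0/1", "0/1"])],
        )
        with pytest.raises(VcfError, match="not sorted"):
            list(read_vcf(vcf, TWO_POP))

    def test_call_rate_filter_drops_exactly_missing_records(self, tmp_path, small_sim, popmap_ab):
        """With min_call_rate=1.0 the reader must drop exactly the records
        whose VCF line contains a missing call, per a direct text scan."""
        from sweepscan.simulate import write_vcf

        vcf = tmp_path / "sim.vcf"
        write_vcf(small_sim, vcf)
        lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        n_total = len(lines)
        n_with_missing = sum("./." in l for l in lines)
        assert n_with_missing > 0  # fixture has missing_rate > 0
        recs = list(read_vcf(vcf, popmap_ab, FilterConfig(min_call_rate=1.0)))
        assert len(recs) == n_total - n_with_missing

    @pytest.mark.parametrize("rates", [(0.0, 0.5), (0.5, 0.9), (0.9, 1.0)])
    def test_filter_monotonicity(self, tmp_path, small_sim, popmap_ab, rates):
        """Tightening min_call_rate never increases the number of records."""
        from sweepscan.simulate import write_vcf

        vcf = tmp_path / "sim.vcf"
        write_vcf(small_sim, vcf)
        loose, tight = rates
        n_loose = len(list(read_vcf(vcf, popmap_ab, FilterConfig(min_call_rate=loose))))
        n_tight = len(list(read_vcf(vcf, popmap_ab, FilterConfig(min_call_rate=tight))))
        assert n_tight <= n_loose


def _record(gts_a, gts_b, ref="A", alt="G", pos=1):
    g = np.array(gts_a + gts_b, dtype=np.int8)
    return SnpRecord("chr1", pos, ref, alt, g)


class TestCountAlleles:
    def test_tie_resolves_to_ref(self):
        rec = _record([(0, 0), (0, 1), (1, 1)], [(0, 0)])
        pm = PopulationMap({"a1": "A", "a2": "A", "a3": "A", "b1": "B"})
        table = count_alleles([rec], pm).df
        assert table.loc[0, "n_major_A"] == 3
        assert table.loc[0, "n_minor_A"] == 3
        assert table.loc[0, "major_A"] == "A"  # tie -> REF

    def test_alt_major(self):
        rec = _record([(1, 1), (1, 1), (0, 1)], [(0, 0)])
        pm = PopulationMap({"a1": "A", "a2": "A", "a3": "A", "b1": "B"})
        table = count_alleles([rec], pm).df
        assert table.loc[0, "n_major_A"] == 5
        assert table.loc[0, "n_minor_A"] == 1
        assert table.loc[0, "major_A"] == "G"

    def test_all_missing_population_flagged(self):
        rec = _record([(-1, -1)], [(0, 1)])
        pm = PopulationMap({"a1": "A", "b1": "B"})
        table = count_alleles([rec], pm).df
        assert table.loc[0, "n_major_A"] == 0 and table.loc[0, "n_minor_A"] == 0
        assert bool(table.loc[0, "all_missing_A"])

    def test_matches_brute_force_tally_on_simulation(self, small_sim, popmap_ab, sim_files):
        """Reader + counter must equal a per-genotype brute-force tally."""
        recs = list(read_vcf(sim_files["vcf"], popmap_ab))
        table = count_alleles(recs, popmap_ab).df
        for i, rec in enumerate(recs[:50]):
            for pop, sl in (("popA", slice(0, 6)), ("popB", slice(6, 12))):
                ref_n = alt_n = 0
                for a, b in rec.genotypes[sl]:
                    for allele in (a, b):
                        if allele == 0:
                            ref_n += 1
                        elif allele == 1:
                            alt_n += 1
                assert table.loc[i, f"n_ref_{pop}"] == ref_n
                assert table.loc[i, f"n_alt_{pop}"] == alt_n
                assert table.loc[i, f"n_major_{pop}"] == max(ref_n, alt_n)
                assert table.loc[i, f"n_minor_{pop}"] == min(ref_n, alt_n)

    def test_allele_count_conservation(self, popmap_ab, sim_files):
        """n_major + n_minor = 2 x non-missing genotypes, every SNP and pop."""
        recs = list(read_vcf(sim_files["vcf"], popmap_ab))
        table = count_alleles(recs, popmap_ab).df
        for i, rec in enumerate(recs):
            for pop, sl in (("popA", slice(0, 6)), ("popB", slice(6, 12))):
                called = int((rec.genotypes[sl] >= 0).all(axis=1).sum())
                total = table.loc[i, f"n_major_{pop}"] + table.loc[i, f"n_minor_{pop}"]
                assert total == 2 * called


class TestClassifySubstitution:
    def test_all_twelve_ordered_pairs(self):
        """4 of the 12 ordered base pairs are transitions, 8 transversions."""
        results = [
            classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        ]
        assert results.count("transition") == 4
        assert results.count("transversion") == 8
        assert classify_substitution("A", "G") == "transition"
        assert classify_substitution("A", "T") == "transversion"

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "G"), ("A", "X")])
    def test_invalid_alleles_fatal(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestSummarizeVariants:
    def test_ts_tv_ratio(self):
        pm = PopulationMap({"a1": "A", "b1": "B"})
        recs = [
            _record([(0, 1)], [(0, 0)], ref="A", alt="G", pos=1),   # ts
            _record([(0, 1)], [(0, 0)], ref="C", alt="T", pos=500),  # ts
            _record([(0, 1)], [(0, 0)], ref="A", alt="T", pos=1000),  # tv
        ]
        summary = summarize_variants(count_alleles(recs, pm), recs)
        assert summary.ts == 2 and summary.tv == 1
        assert summary.ts_tv == pytest.approx(2.0)

    def test_zero_transversions_undefined_not_inf(self):
        pm = PopulationMap({"a1": "A", "b1": "B"})
        recs = [_record([(0, 1)], [(0, 0)], ref="A", alt="G", pos=p) for p in (1, 2)]
        assert summarize_variants(count_alleles(recs, pm), recs).ts_tv is None

    def test_all_homozygous_gives_zero_het_rate(self):
        pm = PopulationMap({"a1": "A", "b1": "B"})
        recs = [
            _record([(0, 0)], [(1, 1)], pos=1),
            _record([(1, 1)], [(0, 0)], pos=2000),
        ]
        summary = summarize_variants(count_alleles(recs, pm), recs)
        assert summary.het_rate_per_kb == {"A": 0.0, "B": 0.0}

    def test_het_rate_matches_hand_count(self, small_sim, popmap_ab, sim_files):
        """Rate equals (het calls / individuals / spanned kb) tallied by hand."""
        recs = list(read_vcf(sim_files["vcf"], popmap_ab))
        counts = count_alleles(recs, popmap_ab)
        summary = summarize_variants(counts, recs)
        span_kb = (counts.df["pos"].max() - counts.df["pos"].min() + 1) / 1000
        het_a = sum(
            1
            for rec in recs
            for a, b in rec.genotypes[:6]
            if a >= 0 and b >= 0 and a != b
        )
        assert summary.het_rate_per_kb["popA"] == pytest.approx(het_a / 6 / span_kb)
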