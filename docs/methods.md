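# Methods

## Problem and model

`sweepscan` detects candidate selective sweeps by contrasting two populations
genotyped at biallelic SNPs. A sweep leaves two genomic signatures the scan
exploits jointly: locally depressed diversity in the swept population
(pooled heterozygosity Hp) and locally elevated differentiation between the
populations (Fst). Both statistics are computed in sliding windows,
Z-standardized against their genome-wide distributions, and thresholded
empirically; there is no parametric null. This is an empirical-outlier scan:
the Z thresholds mark extremeness relative to this genome, not calibrated
significance.

### Pooled heterozygosity

For a window and population, `Hp = 2·S_maj·S_min/(S_maj+S_min)²` with
`S_maj`, `S_min` the sums of the per-SNP major and minor allele counts.
Major/minor are defined *within* the population at each SNP (Hp is an
unpolarized diversity measure); count ties resolve to the REF allele so
output is independent of input ordering. Hp is maximal (0.5) when the summed
counts tie and 0 when every SNP in the window is monomorphic in that
population. Each population gets its own Hp and ZHp track, standardized
separately — the two populations have different diversity levels and each
track answers "extreme for this genome, this population".

### Fst

Per-SNP variance components use REF/ALT-labelled frequencies (labels must be
consistent across populations, unlike Hp's major/minor). Windows combine
components as ratio-of-sums, Σnum/Σden, never a mean of per-SNP ratios
(per-SNP ratios are noisy and their mean is biased). The default estimator
is Hudson's, following the standard recommendation for two-population scans
with modest, possibly unequal sample sizes:

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

SNPs with fewer than 2 called alleles in either population cannot take the
finite-sample correction and are excluded from the window sums (counted, not
silently dropped). The Weir–Cockerham (1984) two-population form on haploid
allele counts is available via `estimator="weir_cockerham"`; for balanced
samples the two agree closely, and both are verified against independent
codings of the published closed forms to 1e-12. Negative per-window Fst
estimates are *not* clamped to 0: clamping would distort the empirical null
the Z-scores are computed from.

### Z-standardization and outlier calling

Each track is standardized as `z = (x − mean)/sd` with mean and sd taken over
unmasked windows genome-wide; the sd is the population form (divide by N).
The convention is documented because it is a convention: at genome scale
(thousands of windows) the ddof choice is immaterial, but fixing it makes
outputs exactly reproducible. Masked windows (fewer than
`min_snps_per_window` usable SNPs, or zero Fst denominator) carry NaN and
never enter the moments.

Three criteria call significant windows, all boundary-inclusive (the
inclusive reading of "exceeding a threshold" is fixed and documented):

1. `ZHp ≤ −5` per population;
2. `ZFst ≥ 4.5`;
3. joint top 1%: `ZHp ≤ Q_1%(ZHp)` **and** `ZFst ≥ Q_99%(ZFst)`, marginal
   linear-interpolation quantiles with conjunction. Only the low-ZHp tail is
   eligible — a sweep means low heterozygosity *and* high differentiation —
   so windows with large positive ZHp are never called.

Overlapping or bookended significant windows merge into candidate regions
(with the default step = window/2, a contiguous sweep signal always yields
one region); each region records its most extreme member Z and window count.

### Annotation

Genes (GFF3 1-based closed, converted to 0-based half-open on import, or BED
used as-is) are assigned to regions by ≥ 1 bp overlap — no flank extension by
default because there is no principled universal flank; a configurable flank
is offered. Over-representation of gene sets is a one-sided hypergeometric
tail P(X ≥ k) with Benjamini–Hochberg adjustment; the default background is
every gene in the annotation.

## Synthetic data generator

The generator emulates the study design the scan targets: two cohorts of 6
diploids each, several chromosomes, background divergence, and planted
sweeps. Per SNP: ancestral ALT frequency p ~ Uniform(0.05, 0.95); population
frequencies from Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = `f_background` (default 0.05, a realistic between-breed divergence);
inside a sweep the target population's frequency is redrawn with
F = `f_sweep` and pushed toward the nearer of {0, 1} so the minor-allele
frequency scales by (1 − diversity_reduction); genotypes are Binomial(2, p)
under HWE; genotypes go missing independently at `missing_rate`. Sites are
resampled until polymorphic across the union of both populations (a VCF
record needs an observed ALT). REF/ALT base pairs are drawn with a 0.70
transition probability, giving a ts/tv ratio near the ~2.3 typical of
mammalian resequencing.

Under this model the expected Hudson window Fst of neutral SNPs is F (the
numerator estimates E[(p1−p2)²] = 2Fp(1−p) given p and the denominator
estimates 2p(1−p)), which the calibration check exploits.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: linkage disequilibrium (sites are independent, so
window statistics are better-behaved than in real genomes and Z thresholds
should be re-examined on real data), mutation-rate and recombination
heterogeneity, genotyping error, reference bias, and the gradual flanking
decay of diversity around a real sweep (planted sweeps have hard edges).
Sites are simulated independently deliberately: the scan consumes per-window
allele frequencies only, and independence keeps the test oracles exact.

## Numerical and design choices

- **Windows**: default 50 kb / 25 kb step, `min_snps_per_window = 10`.
  Candidate regions in studies of this design are 50-kb-aligned and span
  multiples of 25 kb; the SNP floor prevents Z-inflation from near-empty
  windows. Masked windows are reported, never dropped.
- **Boundary semantics**: windows are 0-based half-open; a 1-based SNP at
  pos p belongs to windows with start < p ≤ end. VCF positions stay 1-based;
  every interval output (regions, BED) is 0-based half-open.
- **Degenerate inputs**: zero transversions → ts/tv undefined (None), not
  infinity; all-missing population at a SNP → (0,0) counts, flagged;
  constant Z track or < 2 unmasked windows → fatal with diagnostic; empty
  post-filter VCF → fatal naming the filter stage.
- **Determinism**: one integer seed drives the whole simulation through a
  single PCG64 stream; the same seed yields a byte-identical VCF. The scan
  itself is a pure function of its inputs.

## Problem sizes

The bundled analysis and the acceptance script use a 5 × 10 Mb genome at
1 SNP/kb (50,000 SNPs, 2,000 windows) with 10 planted sweeps of 100 kb at
diversity reduction 0.95 and F_sweep 0.6 — large enough that the joint
top-1% tail (20 windows) must concentrate on real sweeps, small enough to
run in seconds. Estimator exactness is checked on 1,000 random allele-count
configurations; Z normalization on 10,000 simulated windows; interval
algebra on 1,000 randomized instances.

## Known limitations

- Exactly two populations; no haplotype statistics (iHS, XP-EHH) or
  composite-likelihood sweep models.
- Empirical thresholds only — no FDR control or simulation-based null.
- Sensitivity/FDP figures from the generator are upper bounds on real-data
  performance for the reasons above (no LD, hard-edged sweeps).
- The heterozygosity-rate summary (het calls per individual per kb of
  spanned reference) is this package's own definition; published
  "heterozygosity rate" figures from resequencing studies rarely state a
  formula and are not comparable without one.
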