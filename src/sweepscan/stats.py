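"""Window statistics: pooled heterozygosity Hp, Fst, and genome-wide Z-scores.

Hp is the Rubin-style pooled heterozygosity over the SNPs of a window,

    Hp = 2 * S_maj * S_min / (S_maj + S_min)^2,

where S_maj / S_min sum the within-population major / minor allele counts of
the member SNPs; 0 <= Hp <= 0.5, with 0.5 only when the sums tie.

Per-SNP Fst is computed as variance components (numerator, denominator) so
windows can combine them as a ratio of sums — never as a mean of per-SNP
ratios, which is biased. Two estimators are offered:

* Hudson (Bhatia et al. ratio-of-averages form; the default):
      num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      den = p1(1-p2) + p2(1-p1)
  with p the sample ALT frequency and n the number of called alleles.
* Weir & Cockerham (1984), two populations, haploid allele counts with the
  finite-sample correction.

Z-standardization subtracts the genome-wide mean over unmasked windows and
divides by the population standard deviation (ddof=0); masked windows
(too few SNPs, or no usable Fst denominator) get NaN and never enter the
mean/sd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import AlleleCounts
from .windows import WindowSpec

ESTIMATORS = ("hudson", "weir_cockerham")


def pooled_heterozygosity(sum_major: np.ndarray, sum_minor: np.ndarray) -> np.ndarray:
    """Hp = 2*S_maj*S_min/(S_maj+S_min)^2, elementwise; NaN where both sums are 0."""
    sum_major = np.asarray(sum_major, dtype=float)
    sum_minor = np.asarray(sum_minor, dtype=float)
    tot = sum_major + sum_minor
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = 2.0 * sum_major * sum_minor / (tot * tot)
    return np.where(tot > 0, hp, np.nan)


def hudson_components(
    n1_alt: np.ndarray, n1_tot: np.ndarray, n2_alt: np.ndarray, n2_tot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson per-SNP variance components (numerator, denominator, usable mask).

    SNPs with fewer than 2 called alleles in either population cannot take the
    n-1 correction and are flagged unusable.
    """
    n1_tot = np.asarray(n1_tot, dtype=float)
    n2_tot = np.asarray(n2_tot, dtype=float)
    usable = (n1_tot > 1) & (n2_tot > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.asarray(n1_alt, dtype=float) / n1_tot
        p2 = np.asarray(n2_alt, dtype=float) / n2_tot
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1_tot - 1)
            - p2 * (1 - p2) / (n2_tot - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return (
        np.where(usable, num, 0.0),
        np.where(usable, den, 0.0),
        usable,
    )


def weir_cockerham_components(
    n1_alt: np.ndarray, n1_tot: np.ndarray, n2_alt: np.ndarray, n2_tot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) two-population components from haploid allele counts.

    With r=2 samples of n_i alleles at frequencies p_i, weighted mean
    p_bar = sum(n_i p_i)/sum(n_i), n_bar = mean(n_i),
    n_c = (sum(n_i) - sum(n_i^2)/sum(n_i))/(r-1) and
    s2 = sum(n_i (p_i - p_bar)^2) / ((r-1) n_bar):

        a = (n_bar/n_c) * (s2 - (p_bar q_bar - s2/2) / (n_bar - 1))
        b = (n_bar/(n_bar-1)) * (p_bar q_bar - s2/2)

    returning (a, a+b). Requires n_bar > 1 and n_c > 0.
    """
    n1 = np.asarray(n1_tot, dtype=float)
    n2 = np.asarray(n2_tot, dtype=float)
    usable = (n1 > 0) & (n2 > 0) & ((n1 + n2) > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.asarray(n1_alt, dtype=float) / n1
        p2 = np.asarray(n2_alt, dtype=float) / n2
        ntot = n1 + n2
        nbar = ntot / 2.0
        nc = ntot - (n1**2 + n2**2) / ntot  # r-1 = 1
        pbar = (n1 * p1 + n2 * p2) / ntot
        qbar = 1.0 - pbar
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        inner = pbar * qbar - s2 / 2.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * inner
        num = a
        den = a + b
    return (
        np.where(usable, num, 0.0),
        np.where(usable, den, 0.0),
        usable,
    )


def snp_fst_components(
    counts: AlleleCounts, estimator: str = "hudson"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Fst components from an allele-count table, REF/ALT labelled."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; pick from {ESTIMATORS}")
    pop1, pop2 = counts.populations
    df = counts.df
    n1_alt = df[f"n_alt_{pop1}"].to_numpy()
    n1_tot = n1_alt + df[f"n_ref_{pop1}"].to_numpy()
    n2_alt = df[f"n_alt_{pop2}"].to_numpy()
    n2_tot = n2_alt + df[f"n_ref_{pop2}"].to_numpy()
    fn = hudson_components if estimator == "hudson" else weir_cockerham_components
    return fn(n1_alt, n1_tot, n2_alt, n2_tot)


@dataclass
class ZStandardization:
    """Genome-wide moments used for one Z track."""

    mean: float
    sd: float
    n_windows_used: int


def z_standardize(values: np.ndarray) -> tuple[ZStandardization, np.ndarray]:
    """Z-standardize against the genome-wide mean/sd over finite entries.

    NaN entries (masked windows) stay NaN. Uses the population sd (ddof=0).
    Fatal if fewer than 2 usable windows or sd == 0.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n < 2:
        raise ValueError(f"need >= 2 unmasked windows to standardize, got {n}")
    mean = float(values[ok].mean())
    sd = float(values[ok].std(ddof=0))
    if sd == 0:
        raise ValueError("standard deviation over unmasked windows is 0")
    z = np.full_like(values, np.nan)
    z[ok] = (values[ok] - mean) / sd
    return ZStandardization(mean=mean, sd=sd, n_windows_used=n), z


def window_statistics(
    assigned: pd.DataFrame,
    counts: AlleleCounts,
    spec: WindowSpec,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-window Hp (each population), Fst, and genome-wide ZHp / ZFst.

    ``assigned`` is the output of :func:`sweepscan.windows.assign_snps` over the
    SNP table backing ``counts`` (same row order). Windows with fewer than
    ``spec.min_snps_per_window`` usable SNPs are masked: they are reported with
    NaN statistics and excluded from the Z-standardization.

    Returns the Manhattan-plot-ready table with columns chrom, start, end,
    n_snps, hp_<pop>, z_hp_<pop>, fst, z_fst, masked_<pop>, masked_fst.
    """
    pop1, pop2 = counts.populations
    df = counts.df
    lo = assigned["lo"].to_numpy()
    hi = assigned["hi"].to_numpy()

    def window_sum(per_snp: np.ndarray) -> np.ndarray:
        csum = np.concatenate([[0.0], np.cumsum(per_snp, dtype=float)])
        return csum[hi] - csum[lo]

    out = assigned[["chrom", "start", "end", "n_snps"]].copy()
    n_snps = out["n_snps"].to_numpy()
    masked_n = n_snps < spec.min_snps_per_window

    for pop in (pop1, pop2):
        s_maj = window_sum(df[f"n_major_{pop}"].to_numpy())
        s_min = window_sum(df[f"n_minor_{pop}"].to_numpy())
        hp = pooled_heterozygosity(s_maj, s_min)
        masked = masked_n | ~np.isfinite(hp)
        hp = np.where(masked, np.nan, hp)
        out[f"hp_{pop}"] = hp
        out[f"masked_{pop}"] = masked

    num, den, usable = snp_fst_components(counts, estimator)
    w_num = window_sum(num)
    w_den = window_sum(den)
    w_usable = window_sum(usable.astype(float))
    masked_fst = masked_n | (w_den == 0) | (w_usable < spec.min_snps_per_window)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(masked_fst, np.nan, w_num / np.where(w_den == 0, np.nan, w_den))
    out["fst"] = fst
    out["masked_fst"] = masked_fst

    for pop in (pop1, pop2):
        _, z = z_standardize(out[f"hp_{pop}"].to_numpy())
        out[f"z_hp_{pop}"] = z
    _, zf = z_standardize(out["fst"].to_numpy())
    out["z_fst"] = zf
    return out
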