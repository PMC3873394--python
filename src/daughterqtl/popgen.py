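"""Descriptive SNP statistics: genotype/allele frequencies, Hardy-Weinberg
equilibrium screening and Bonferroni thresholds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, SnpMap


@dataclass
class SnpSummary:
    """Per-SNP genotype counts/frequencies, MAF, HWE test and call rate."""

    snp_id: str
    genotype_counts: tuple[int, int, int]     # copies of minor allele: 0, 1, 2
    genotype_freqs: tuple[float, float, float]
    minor_allele: str
    maf: float
    hwe_chisq: float
    hwe_p: float
    call_rate: float


def snp_summary(genotypes: GenotypeMatrix, snp: int,
                snp_map: SnpMap | None = None) -> SnpSummary:
    """Summarise one SNP over non-missing individuals.

    MAF = f(het)/2 + f(minor homozygote); because codes count the minor
    allele this is simply the mean code / 2.
    """
    col = genotypes.codes[:, snp]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"SNP index {snp}: all genotypes missing")
    n0, n1, n2 = (int(np.sum(obs == k)) for k in (0, 1, 2))
    total = n0 + n1 + n2
    freqs = (n0 / total, n1 / total, n2 / total)
    maf = freqs[1] / 2.0 + freqs[2]
    chisq, p = hwe_test((n0, n1, n2))
    minor = ""
    if snp_map is not None and snp_map.minor_allele:
        minor = snp_map.minor_allele[snp]
    return SnpSummary(
        snp_id=snp_map.snp_id[snp] if snp_map is not None else str(snp),
        genotype_counts=(n0, n1, n2), genotype_freqs=freqs,
        minor_allele=minor, maf=maf, hwe_chisq=chisq, hwe_p=p,
        call_rate=total / genotypes.n_individuals)


def hwe_test(genotype_counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions, df = 1.

    Expected counts come from the sample allele frequencies; no continuity
    correction.  A monomorphic locus returns (0, 1) rather than erroring.
    """
    n11, n12, n22 = genotype_counts
    n = n11 + n12 + n22
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n11 + n12) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n11, n12, n22], dtype=float)
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    return chisq, float(stats.chi2.sf(chisq, df=1))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def summary_table(genotypes: GenotypeMatrix, snp_map: SnpMap) -> pd.DataFrame:
    """Genotype-frequency / MAF / HWE table over all SNPs.

    Frequencies are rounded to 3 decimals for reporting; the underlying
    SnpSummary objects carry full precision.
    """
    rows = []
    for j in range(genotypes.n_snps):
        s = snp_summary(genotypes, j, snp_map)
        rows.append({
            "snp_id": s.snp_id,
            "chromosome": snp_map.chromosome[j],
            "position": int(snp_map.position[j]),
            "n_major_hom": s.genotype_counts[0],
            "n_het": s.genotype_counts[1],
            "n_minor_hom": s.genotype_counts[2],
            "freq_major_hom": round(s.genotype_freqs[0], 3),
            "freq_het": round(s.genotype_freqs[1], 3),
            "freq_minor_hom": round(s.genotype_freqs[2], 3),
            "minor_allele": s.minor_allele,
            "maf": round(s.maf, 3),
            "hwe_chisq": s.hwe_chisq,
            "hwe_p": s.hwe_p,
            "call_rate": round(s.call_rate, 3),
        })
    return pd.DataFrame(rows)
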