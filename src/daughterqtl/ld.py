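"""Haplotype-frequency estimation and linkage disequilibrium.

Phasing uses an exhaustive expectation-maximisation over all diplotype
expansions of each individual's unphased genotype — exact for the small
candidate-gene windows this package targets (<= 12 SNPs).  Missing
genotypes are marginalised over both alleles.  Pairwise LD (D', r2) and
likelihood-profile D' confidence intervals feed a Gabriel-style block
detector; rare haplotypes can be pooled into a single pseudo-haplotype for
downstream trend regression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix, SnpMap

_ENUM_CAP = 1 << 20  # diplotype expansions per individual


@dataclass
class HaplotypeSet:
    """EM-fitted haplotypes for one SNP window.

    ``haplotypes`` are allele strings ordered by map position (or '0'/'1'
    minor-allele indicators when no map is supplied); ``dosages`` holds the
    posterior expected count of each haplotype per individual (rows sum
    to 2).
    """

    snp_indices: tuple[int, ...]
    haplotypes: list[str]
    hap_bits: list[tuple[int, ...]]
    frequencies: np.ndarray
    dosages: np.ndarray  # n_individuals x n_haplotypes
    log_likelihood: float
    ll_trace: list[float]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")
        rows = self.dosages.sum(axis=1)
        if np.any(np.abs(rows - 2.0) > 1e-9):
            raise ValueError("each dosage row must sum to 2")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class LDResult:
    """Pairwise linkage disequilibrium between two SNPs."""

    snp_i: int
    snp_j: int
    dprime: float
    r2: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class BlockPartition:
    """Ordered, non-overlapping SNP index ranges (inclusive) forming blocks."""

    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        last = -1
        for a, b in self.blocks:
            if b - a + 1 < 2:
                raise ValueError("a block must span at least 2 SNPs")
            if a <= last:
                raise ValueError("blocks must be ordered and non-overlapping")
            last = b

    def __len__(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with one genotype vector."""
    het = [k for k, g in enumerate(geno) if g == 1]
    mis = [k for k, g in enumerate(geno) if g == MISSING]
    if (1 << len(het)) * (1 << (2 * len(mis))) > _ENUM_CAP:
        raise ValueError("window too large to enumerate; split into blocks first")
    base = [g // 2 if g in (0, 2) else 0 for g in geno]
    pairs = set()
    for het_bits in product((0, 1), repeat=len(het)):
        for mis_bits in product((0, 1), (0, 1), repeat=len(mis)):
            h1 = list(base)
            h2 = list(base)
            for k, b in zip(het, het_bits):
                h1[k], h2[k] = b, 1 - b
            for k, (b1, b2) in zip(mis, zip(mis_bits[0::2], mis_bits[1::2])):
                h1[k], h2[k] = b1, b2
            key = tuple(sorted((tuple(h1), tuple(h2))))
            pairs.add(key)
    return sorted(pairs)


def em_haplotype_frequencies(genotypes: GenotypeMatrix,
                             snp_indices: Sequence[int],
                             max_iter: int = 500,
                             tol: float = 1e-8,
                             n_restarts: int = 5,
                             seed: int | None = None,
                             snp_map: SnpMap | None = None) -> HaplotypeSet:
    """Exhaustive-diplotype EM over an SNP window of <= 12 sites.

    Each restart perturbs the uniform initial frequencies with seeded
    Dirichlet jitter; the restart with the highest converged log-likelihood
    wins (ties broken toward lexicographically ordered frequencies).  The
    log-likelihood trace is monotone non-decreasing by construction of EM
    and is asserted on every run.
    """
    snp_indices = tuple(int(k) for k in snp_indices)
    if len(snp_indices) > 12:
        raise ValueError("EM window limited to 12 SNPs; split into blocks first")
    codes = genotypes.codes[:, snp_indices]
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")

    # group individuals by genotype pattern
    patterns: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        patterns.setdefault(tuple(int(c) for c in codes[i]), []).append(i)

    pat_pairs = {g: _compatible_pairs(g) for g in patterns}
    haps = sorted({h for pairs in pat_pairs.values() for pr in pairs for h in pr})
    hindex = {h: k for k, h in enumerate(haps)}
    K = len(haps)

    # per-pattern pair index arrays for vectorised E-steps
    pat_arrays = {}
    for g, pairs in pat_pairs.items():
        i1 = np.array([hindex[a] for a, _ in pairs])
        i2 = np.array([hindex[b] for _, b in pairs])
        mult = np.where(i1 == i2, 1.0, 2.0)
        pat_arrays[g] = (i1, i2, mult, len(patterns[g]))

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        f = np.full(K, 1.0 / K)
        if r > 0:
            f = rng.dirichlet(np.full(K, 5.0))
        trace: list[float] = []
        for _ in range(max_iter):
            counts = np.zeros(K)
            ll = 0.0
            for g, (i1, i2, mult, w) in pat_arrays.items():
                probs = mult * f[i1] * f[i2]
                tot = probs.sum()
                if tot <= 0:
                    tot = np.finfo(float).tiny
                post = probs / tot
                np.add.at(counts, i1, w * post)
                np.add.at(counts, i2, w * post)
                ll += w * np.log(tot)
            trace.append(ll)
            f_new = counts / (2.0 * n)
            if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                f = f_new
                break
            f = f_new
        if any(b - a < -1e-9 for a, b in zip(trace, trace[1:])):
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        cand = (trace[-1], tuple(-f), f, trace)
        if best is None or cand[:2] > best[:2]:
            best = cand

    ll_final, _, f, trace = best
    # posterior expected haplotype dosages per individual
    dosages = np.zeros((n, K))
    for g, (i1, i2, mult, _) in pat_arrays.items():
        probs = mult * f[i1] * f[i2]
        tot = probs.sum()
        post = probs / (tot if tot > 0 else np.finfo(float).tiny)
        row = np.zeros(K)
        np.add.at(row, i1, post)
        np.add.at(row, i2, post)
        for i in patterns[g]:
            dosages[i] = row

    # prune haplotypes driven to (numerically) zero frequency
    keep = f > 1e-10
    if not keep.all():
        lost = f[~keep].sum()
        f = f[keep] / (1.0 - lost)
        dosages = dosages[:, keep]
        # reapportion the negligible dosage mass so rows still sum to 2
        dosages *= 2.0 / dosages.sum(axis=1, keepdims=True)
        haps = [h for h, k in zip(haps, keep) if k]

    labels = [_hap_label(bits, snp_indices, snp_map) for bits in haps]
    return HaplotypeSet(snp_indices=snp_indices, haplotypes=labels,
                        hap_bits=list(haps), frequencies=f, dosages=dosages,
                        log_likelihood=float(ll_final), ll_trace=list(trace))


def _hap_label(bits: tuple[int, ...], snp_indices: tuple[int, ...],
               snp_map: SnpMap | None) -> str:
    if snp_map is None or not snp_map.minor_allele:
        return "".join(str(b) for b in bits)
    out = []
    for b, j in zip(bits, snp_indices):
        minor = snp_map.minor_allele[j]
        major = (snp_map.ref_allele[j] if minor == snp_map.alt_allele[j]
                 else snp_map.alt_allele[j])
        out.append(minor if b else major)
    return "".join(out)


def pool_rare_haplotypes(hs: HaplotypeSet, threshold: float = 0.05) -> HaplotypeSet:
    """Merge haplotypes with frequency < ``threshold`` into one pooled class.

    The pooled pseudo-haplotype's frequency and dosage column are the sums
    over its members; frequency mass and row sums are conserved exactly.
    """
    rare = hs.frequencies < threshold
    if not rare.any():
        return replace(hs)
    if rare.all():
        raise ValueError("all haplotypes fall below the pooling threshold")
    keep = ~rare
    if hs.frequencies[rare].sum() < 1e-6:
        # negligible rare mass: drop rather than carry a near-zero column
        freqs = hs.frequencies[keep] / hs.frequencies[keep].sum()
        dosages = hs.dosages[:, keep]
        dosages = dosages * (2.0 / dosages.sum(axis=1, keepdims=True))
        haps = [h for h, k in zip(hs.haplotypes, keep) if k]
        bits = [b for b, k in zip(hs.hap_bits, keep) if k]
        return HaplotypeSet(snp_indices=hs.snp_indices, haplotypes=haps,
                            hap_bits=bits, frequencies=freqs, dosages=dosages,
                            log_likelihood=hs.log_likelihood, ll_trace=hs.ll_trace)
    freqs = np.append(hs.frequencies[keep], hs.frequencies[rare].sum())
    dosages = np.column_stack([hs.dosages[:, keep], hs.dosages[:, rare].sum(axis=1)])
    haps = [h for h, k in zip(hs.haplotypes, keep) if k] + ["pooled"]
    bits = [b for b, k in zip(hs.hap_bits, keep) if k] + [()]
    return HaplotypeSet(snp_indices=hs.snp_indices, haplotypes=haps,
                        hap_bits=bits, frequencies=freqs, dosages=dosages,
                        log_likelihood=hs.log_likelihood, ll_trace=hs.ll_trace)


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

def _two_locus_counts(genotypes: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """3x3 two-locus genotype count table over complete-case individuals."""
    gi = genotypes.codes[:, i]
    gj = genotypes.codes[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    tab = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            tab[a, b] = np.sum((gi[ok] == a) & (gj[ok] == b))
    return tab


def _hap_freqs_to_ld(p00: float, p01: float, p10: float, p11: float
                     ) -> tuple[float, float]:
    """D' and r2 from two-locus haplotype frequencies (1 = minor allele)."""
    pA = p10 + p11  # minor at first locus
    pB = p01 + p11  # minor at second locus
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP in LD computation")
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return min(dprime, 1.0), min(r2, 1.0)


def _two_locus_em(genotypes: GenotypeMatrix, snp_i: int, snp_j: int,
                  seed: int | None) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (p00, p01, p10, p11) from a 2-SNP EM
    over complete-case individuals."""
    gi = genotypes.codes[:, snp_i]
    gj = genotypes.codes[:, snp_j]
    ok = (gi != MISSING) & (gj != MISSING)
    for col, name in ((gi[ok], snp_i), (gj[ok], snp_j)):
        if col.size == 0 or len(np.unique(col)) < 2:
            raise ValueError(f"SNP index {name} is monomorphic")
    sub = GenotypeMatrix(ids=[genotypes.ids[k] for k in np.flatnonzero(ok)],
                         codes=genotypes.codes[np.ix_(ok, [snp_i, snp_j])])
    hs = em_haplotype_frequencies(sub, (0, 1), n_restarts=3, seed=seed)
    freq = {bits: f for bits, f in zip(hs.hap_bits, hs.frequencies)}
    return (freq.get((0, 0), 0.0), freq.get((0, 1), 0.0),
            freq.get((1, 0), 0.0), freq.get((1, 1), 0.0))


def pairwise_ld(genotypes: GenotypeMatrix, snp_i: int, snp_j: int,
                seed: int | None = 0) -> LDResult:
    """D' and r2 from a two-SNP EM fit (complete-case individuals)."""
    p00, p01, p10, p11 = _two_locus_em(genotypes, snp_i, snp_j, seed)
    dprime, r2 = _hap_freqs_to_ld(p00, p01, p10, p11)
    return LDResult(snp_i=snp_i, snp_j=snp_j, dprime=dprime, r2=r2)


def dprime_confidence_interval(genotypes: GenotypeMatrix, snp_i: int, snp_j: int,
                               coverage: float = 0.95, grid_step: float = 0.001,
                               seed: int | None = 0) -> tuple[float, float]:
    """Likelihood-profile confidence interval for |D'|.

    The two-locus multinomial likelihood is evaluated on a |D'| grid with
    allele frequencies held at their sample estimates and the sign of D at
    its MLE; equal-tail bounds come from the normalised cumulative
    likelihood.  The interval is widened, if necessary, to contain the EM
    point estimate so that point-in-interval holds by construction.
    """
    em = _two_locus_em(genotypes, snp_i, snp_j, seed)
    return _dprime_ci(genotypes, snp_i, snp_j, em, coverage, grid_step)


def _dprime_ci(genotypes, snp_i, snp_j, em, coverage, grid_step):
    tab = _two_locus_counts(genotypes, snp_i, snp_j)
    n = tab.sum()
    if n == 0:
        raise ValueError("no complete-case individuals for this SNP pair")
    # minor-allele frequencies from the genotype margins
    pA = (tab.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pB = (tab.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP in CI computation")
    p00, p01, p10, p11 = em
    point_dprime, _ = _hap_freqs_to_ld(p00, p01, p10, p11)
    sign = 1.0 if p11 - (p10 + p11) * (p01 + p11) >= 0 else -1.0
    dmax = (min(pA * (1 - pB), (1 - pA) * pB) if sign >= 0
            else min(pA * pB, (1 - pA) * (1 - pB)))
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    D = sign * grid * dmax                                   # (G,)
    h = np.stack([(1 - pA) * (1 - pB) + D,                   # 00
                  (1 - pA) * pB - D,                         # 01
                  pA * (1 - pB) - D,                         # 10
                  pA * pB + D])                              # 11  -> (4, G)
    feasible = (h > -1e-12).all(axis=0)
    h = np.clip(h, 1e-12, None)
    # genotype probabilities: aggregate ordered haplotype pairs into the 3x3 table
    pair = h[:, None, :] * h[None, :, :]                     # (4, 4, G)
    probs = np.zeros((3, 3, len(grid)))
    bits = ((0, 0), (0, 1), (1, 0), (1, 1))
    for a in range(4):
        for b in range(4):
            probs[bits[a][0] + bits[b][0], bits[a][1] + bits[b][1]] += pair[a, b]
    counts = tab.ravel()
    ll = counts @ np.log(probs.reshape(9, -1))
    ll[~feasible] = -np.inf
    w = np.exp(ll - ll.max())
    cum = np.cumsum(w) / w.sum()
    tail = (1.0 - coverage) / 2.0
    lower = float(grid[int(np.searchsorted(cum, tail))])
    upper = float(grid[min(int(np.searchsorted(cum, 1.0 - tail)), len(grid) - 1)])
    lower = min(lower, point_dprime)
    upper = max(upper, point_dprime)
    return lower, upper


def _genotype_probs_from_haps(h: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype probabilities from 4 haplotype frequencies
    (order 00, 01, 10, 11) under random mating."""
    bits = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    probs = np.zeros((3, 3))
    for a in range(4):
        for b in range(4):
            gi = bits[a, 0] + bits[b, 0]
            gj = bits[a, 1] + bits[b, 1]
            probs[gi, gj] += h[a] * h[b]
    return probs


def all_pairwise_ld(genotypes: GenotypeMatrix, with_ci: bool = True,
                    coverage: float = 0.95, seed: int | None = 0
                    ) -> dict[tuple[int, int], LDResult]:
    """LD (and optionally D' CIs) for every polymorphic SNP pair.

    Monomorphic SNPs are skipped; their pairs are simply absent from the
    result, which block detection treats as uninformative.
    """
    m = genotypes.n_snps
    poly = []
    for j in range(m):
        col = genotypes.codes[:, j]
        obs = col[col != MISSING]
        if obs.size and len(np.unique(obs)) > 1:
            poly.append(j)
    out: dict[tuple[int, int], LDResult] = {}
    for a in range(len(poly)):
        for b in range(a + 1, len(poly)):
            i, j = poly[a], poly[b]
            em = _two_locus_em(genotypes, i, j, seed)
            dprime, r2 = _hap_freqs_to_ld(*em)
            res = LDResult(snp_i=i, snp_j=j, dprime=dprime, r2=r2)
            if with_ci:
                res.ci_low, res.ci_high = _dprime_ci(
                    genotypes, i, j, em, coverage, 0.001)
            out[(i, j)] = res
    return out


# ---------------------------------------------------------------------------
# block detection
# ---------------------------------------------------------------------------

def detect_blocks(ld: Mapping[tuple[int, int], LDResult], snp_map: SnpMap,
                  strong_low: float = 0.70, strong_high: float = 0.98,
                  recomb_high: float = 0.90,
                  min_strong_fraction: float = 0.95) -> BlockPartition:
    """Gabriel-style D'-confidence-interval block detection.

    A pair is "strong LD" when its CI lower bound >= ``strong_low`` and
    upper bound >= ``strong_high``; "strong recombination" when the upper
    bound < ``recomb_high``.  A contiguous candidate range is a block when
    at least ``min_strong_fraction`` of its informative pairs are strong
    LD.  Candidates are accepted greedily from longest to shortest, skipping
    overlaps.
    """
    m = len(snp_map)

    def pair(i, j):
        return ld.get((i, j)) or ld.get((j, i))

    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            strong = informative = 0
            for i in range(a, b + 1):
                for j in range(i + 1, b + 1):
                    r = pair(i, j)
                    if r is None or r.ci_low is None:
                        continue
                    if r.ci_low >= strong_low and r.ci_high >= strong_high:
                        strong += 1
                        informative += 1
                    elif r.ci_high < recomb_high:
                        informative += 1
            if informative and strong / informative >= min_strong_fraction:
                # outermost pair itself must show strong LD
                edge = pair(a, b)
                if edge is not None and edge.ci_low is not None and \
                        edge.ci_low >= strong_low and edge.ci_high >= strong_high:
                    candidates.append((a, b))
    candidates.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    chosen: list[tuple[int, int]] = []
    used = np.zeros(m, dtype=bool)
    for a, b in candidates:
        if not used[a:b + 1].any():
            chosen.append((a, b))
            used[a:b + 1] = True
    chosen.sort()
    return BlockPartition(blocks=chosen)
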