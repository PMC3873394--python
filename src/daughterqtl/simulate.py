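"""Synthetic half-sib daughter-design datasets.

The generator emulates the study design the analysis stack assumes: a
modest number of progeny-tested sires, each with a group of genotyped
daughters whose dams are unknown and unrelated; a candidate-gene SNP panel
organised into tight LD blocks (haplotypes gene-dropped without
within-block recombination, blocks segregating independently); EBV
phenotypes built from a causal SNP effect, a pedigree-correlated polygenic
term and reliability-scaled noise, exactly matching the residual model the
mixed-model weight matrix assumes; and genotype-dependent qPCR expression
data.  All outputs are deterministic in (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .io import GenotypeMatrix, Pedigree, PhenotypeTable, SnpMap, UNKNOWN
from .io import _orient_to_minor  # same minor-allele convention as the readers

TRAITS = ("MY", "FY", "PY", "FP", "PP")

_ALLELE_CYCLE = (("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"), ("G", "C"),
                 ("A", "G"), ("C", "A"))


@dataclass
class BlockSpec:
    """One LD block: haplotypes as 0/1 strings over its SNPs, plus their
    pool frequencies.  A single-SNP 'block' is an independent SNP."""

    haplotypes: Sequence[str]
    frequencies: Sequence[float]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ValueError("haplotype pool frequencies must be >= 0 and sum to 1")
        lens = {len(h) for h in self.haplotypes}
        if len(lens) != 1:
            raise ValueError("haplotypes in a block must have equal length")

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0])

    @property
    def bits(self) -> np.ndarray:
        return np.array([[int(c) for c in h] for h in self.haplotypes])


def _default_blocks() -> list[BlockSpec]:
    """13 SNPs: two tight blocks (5 + 2 SNPs) among independent SNPs, with
    frequencies shaped like a real candidate-gene panel."""
    def snp(maf):
        return BlockSpec(haplotypes=("0", "1"), frequencies=(1 - maf, maf))
    block1 = BlockSpec(
        haplotypes=("00000", "10000", "01111", "00111"),
        frequencies=(0.34, 0.33, 0.26, 0.07))
    block2 = BlockSpec(haplotypes=("00", "10", "01"),
                       frequencies=(0.44, 0.388, 0.172))
    return [snp(0.38), snp(0.05), snp(0.45), block1, snp(0.27),
            block2, snp(0.17), snp(0.28)]


@dataclass
class SimulationConfig:
    """Study-scale defaults: 14 sires, 638 daughters, 13 SNPs in 2 blocks."""

    n_sires: int = 14
    daughters_per_sire: int | Sequence[int] = field(
        default_factory=lambda: tuple([46] * 8 + [45] * 6))  # 638 daughters
    block_specs: list[BlockSpec] = field(default_factory=_default_blocks)
    causal_snp: int | None = 4          # second SNP of the 5-SNP block
    alpha_true: float = 0.5             # trait units per minor-allele copy
    var_a: float = 1.0
    var_e: float = 1.0
    reliability_range: tuple[float, float] = (0.5, 0.95)
    mu: float = 0.0
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        # var_a = 0 (no polygenic background) is a legitimate degenerate case
        # for the generator; the analysis-side VarianceComponents stays strict
        if self.var_a < 0 or self.var_e <= 0:
            raise ValueError("need var_a >= 0 and var_e > 0")
        lo, hi = self.reliability_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("reliability range must sit inside (0, 1]")

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.block_specs)

    @property
    def var_p(self) -> float:
        return self.var_a + self.var_e


@dataclass
class SimulationTruth:
    """Ground truth stored alongside every generated dataset."""

    alpha_true: float
    causal_snp: int | None
    true_breeding_values: pd.DataFrame   # individuals x traits
    phases: list[np.ndarray]             # per block: (n, 2) pool haplotype idx
    realized_var_explained: dict[str, float]


def simulate_pedigree(n_sires: int, daughters_per_sire: int | Sequence[int],
                      seed: int | None = None) -> Pedigree:
    """Half-sib families: each daughter has a known sire, unknown dam."""
    if n_sires < 1:
        raise ValueError("need at least one sire")
    if isinstance(daughters_per_sire, (int, np.integer)):
        counts = [int(daughters_per_sire)] * n_sires
    else:
        counts = [int(c) for c in daughters_per_sire]
        if len(counts) != n_sires:
            raise ValueError("daughters_per_sire list must have n_sires entries")
    if min(counts) < 1:
        raise ValueError("each sire needs at least one daughter")
    records = [(f"S{k + 1}", UNKNOWN, UNKNOWN) for k in range(n_sires)]
    d = 0
    for k, c in enumerate(counts):
        for _ in range(c):
            d += 1
            records.append((f"D{d}", f"S{k + 1}", UNKNOWN))
    return Pedigree.from_records(records)


def _default_snp_map(config: SimulationConfig) -> SnpMap:
    m = config.n_snps
    refs, alts = [], []
    for j in range(m):
        r, a = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
        refs.append(r)
        alts.append(a)
    return SnpMap(snp_id=[f"M{j + 1}" for j in range(m)],
                  chromosome=["14"] * m,
                  position=100_000 + 5_000 * np.arange(m),
                  ref_allele=refs, alt_allele=alts)


def simulate_genotypes(ped: Pedigree, config: SimulationConfig,
                       seed: int | None = None
                       ) -> tuple[GenotypeMatrix, SnpMap, list[np.ndarray]]:
    """Gene-drop block haplotypes down the pedigree.

    Founders draw two pool haplotypes per block; non-founders inherit one
    haplotype from each parent (a missing parent contributes a fresh pool
    draw, matching the unknown unrelated dams of a daughter design).
    Blocks segregate independently; there is no recombination within a
    block, so every carried haplotype is a pool member.  Codes are oriented
    to count the sample minor allele, as the genotype readers do.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    phases: list[np.ndarray] = []
    cols = []
    for spec in config.block_specs:
        freqs = np.asarray(spec.frequencies, dtype=float)
        bits = spec.bits
        ph = np.zeros((n, 2), dtype=int)
        for i in range(n):
            for m, parent in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
                if parent < 0:
                    ph[i, m] = rng.choice(len(freqs), p=freqs)
                else:
                    ph[i, m] = ph[parent, rng.integers(2)]
        phases.append(ph)
        cols.append(bits[ph[:, 0]] + bits[ph[:, 1]])
    codes_alt = np.concatenate(cols, axis=1).astype(np.int8)
    smap = _default_snp_map(config)
    gm, smap = _orient_to_minor(list(ped.ids), codes_alt, smap)
    return gm, smap, phases


def simulate_ebv_phenotypes(ped: Pedigree, genotypes: GenotypeMatrix,
                            config: SimulationConfig, seed: int | None = None
                            ) -> tuple[PhenotypeTable, SimulationTruth]:
    """EBV phenotypes y = mu + x alpha + a + e per trait.

    Polygenic values are gene-dropped: founder a ~ N(0, s2a); an offspring
    gets half of each known parent's value plus Mendelian sampling with
    variance s2a (1 - 0.25 * n_known_parents), treating unknown parents as
    non-inbred unrelated founders.  Residuals are N(0, s2e / REL_i) with
    REL_i uniform on the configured range and shared across traits — the
    exact residual model the analysis weight matrix assumes.  Traits are
    independent (no genetic correlations).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    rel = rng.uniform(*config.reliability_range, size=n)
    x = np.zeros(n)
    if config.causal_snp is not None:
        x = genotypes.codes[:, config.causal_snp].astype(float)
        x[x < 0] = 0.0
    bv = {}
    rows = []
    realized_ve = {}
    for trait in config.traits:
        a = np.zeros(n)
        ms_sd = {2: np.sqrt(config.var_a * 0.5),
                 1: np.sqrt(config.var_a * 0.75),
                 0: np.sqrt(config.var_a)}
        noise = rng.standard_normal(n)
        for i in range(n):
            known = 0
            mid = 0.0
            for parent in (ped.sire_idx[i], ped.dam_idx[i]):
                if parent >= 0:
                    known += 1
                    mid += 0.5 * a[parent]
            a[i] = mid + ms_sd[known] * noise[i]
        e = rng.standard_normal(n) * np.sqrt(config.var_e / rel)
        y = config.mu + x * config.alpha_true + a + e
        bv[trait] = a.copy()
        var_snp = np.var(x * config.alpha_true)
        realized_ve[trait] = float(var_snp / config.var_p)
        for i, iid in enumerate(ped.ids):
            rows.append({"id": iid, "trait": trait, "ebv": y[i],
                         "reliability": rel[i]})
    table = PhenotypeTable(pd.DataFrame(rows))
    truth = SimulationTruth(
        alpha_true=config.alpha_true, causal_snp=config.causal_snp,
        true_breeding_values=pd.DataFrame(bv, index=list(ped.ids)),
        phases=[], realized_var_explained=realized_ve)
    return table, truth


def simulate_expression(genotype_groups: Mapping[str, tuple[float, float, int]],
                        seed: int | None = None, n_replicates: int = 3,
                        ct_reference: float = 20.0, tech_sd: float = 0.0
                        ) -> ExpressionTable:
    """Ct-scale qPCR data whose relative-expression group means match the
    requested means in expectation.

    Each sample's relative quantity is drawn Normal(mean, sd) truncated
    away from zero and encoded as dCt = -log2(RQ) on top of a flat
    reference-gene Ct; technical replicates (default 3) can carry optional
    Ct-scale noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, (mean, sd, n) in genotype_groups.items():
        if sd < 0 or n < 1:
            raise ValueError("group sd must be >= 0 and n >= 1")
        if mean <= 0:
            raise ValueError("relative-expression means must be positive")
        for k in range(n):
            rq = mean if sd == 0 else max(rng.normal(mean, sd), mean * 1e-3)
            dct = -np.log2(rq)
            for r in range(n_replicates):
                jitter = rng.normal(0.0, tech_sd) if tech_sd > 0 else 0.0
                rows.append({"sample_id": f"{group}_{k + 1}", "group": group,
                             "ct_target": ct_reference + dct + jitter,
                             "ct_reference": ct_reference,
                             "replicate": r + 1})
    return ExpressionTable(pd.DataFrame(rows))


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None):
    """One full dataset: pedigree, genotypes+map, phenotypes, truth.

    Stage seeds are spawned from the global seed so each stage has an
    independent, reproducible stream.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    s_ped, s_gen, s_phe = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in ss.spawn(3))
    ped = simulate_pedigree(config.n_sires, config.daughters_per_sire, s_ped)
    gm, smap, phases = simulate_genotypes(ped, config, s_gen)
    phen, truth = simulate_ebv_phenotypes(ped, gm, config, s_phe)
    truth.phases = phases
    return ped, gm, smap, phen, truth
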