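"""Association testing on EBV phenotypes.

Single-locus scans regress EBVs on minor-allele dosage (0/1/2) inside the
pedigree mixed model and test the regression coefficient with a Wald
chi-square on 1 df.  Haplotype trend regression replaces the dosage with
per-individual expected haplotype counts and tests all non-reference
haplotype effects jointly on k-1 df.  Variance explained by a locus is
reported as 2p(1-p)alpha^2 / sigma2_P, the classical allele-substitution
decomposition on the phenotypic scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, AssociationResult, GenotypeMatrix, Pedigree, PhenotypeTable, SnpMap
from .kinship import inverse_relationship_matrix
from .ld import HaplotypeSet
from .mixed_model import PedigreeMixedLM, VarianceComponents
from .popgen import bonferroni_threshold

logger = logging.getLogger(__name__)


def variance_explained(maf: float, alpha_hat: float, var_p: float) -> float:
    """Fraction of phenotypic variance explained: 2 p (1-p) alpha^2 / var_p."""
    if not (0.0 < maf < 1.0):
        raise ValueError("allele frequency must be in (0, 1)")
    if var_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return 2.0 * maf * (1.0 - maf) * alpha_hat ** 2 / var_p


def _aligned_data(genotypes: GenotypeMatrix, phen: pd.DataFrame,
                  snp: int | None = None):
    """Intersect genotyped and phenotyped individuals; drop missing calls."""
    gpos = {iid: k for k, iid in enumerate(genotypes.ids)}
    pid = phen["id"].astype(str).to_numpy()
    gidx = np.array([gpos.get(i, -1) for i in pid], dtype=int)
    keep = gidx >= 0
    if snp is not None:
        keep &= np.where(keep, genotypes.codes[gidx, snp] != MISSING, False)
    ids = [i for i, k in zip(pid, keep) if k]
    return (ids, phen["ebv"].to_numpy(dtype=float)[keep],
            phen["reliability"].to_numpy(dtype=float)[keep], gidx[keep])


def single_snp_scan(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                    ped: Pedigree, vc: VarianceComponents, trait: str,
                    snp_map: SnpMap | None = None, alpha: float = 0.05,
                    a_inv: np.ndarray | None = None,
                    snps: list[int] | None = None) -> list[AssociationResult]:
    """Per-SNP dosage regression with polygenic control.

    Individuals missing the genotype at a SNP are dropped for that SNP
    only.  Monomorphic SNPs yield p = 1 with a logged warning instead of a
    hard error.  Bonferroni significance is judged at alpha / n_snps over
    the SNPs actually scanned.
    """
    phen = phenotypes.for_trait(trait)
    if a_inv is None:
        a_inv = inverse_relationship_matrix(ped)
    snps = list(range(genotypes.n_snps)) if snps is None else list(snps)
    threshold = bonferroni_threshold(alpha, len(snps))
    results: list[AssociationResult] = []
    for j in snps:
        sid = snp_map.snp_id[j] if snp_map is not None else f"snp{j}"
        ids, y, rel, gidx = _aligned_data(genotypes, phen, snp=j)
        x = genotypes.codes[gidx, j].astype(float)
        maf = x.mean() / 2.0 if len(x) else 0.0
        if len(np.unique(x)) < 2:
            logger.warning("SNP %s monomorphic in analysed individuals; p set to 1", sid)
            results.append(AssociationResult(sid, 0.0, np.nan, 0.0, 1, 1.0,
                                             threshold, False, 0.0))
            continue
        X = np.column_stack([np.ones_like(x), x])
        model = PedigreeMixedLM.from_pedigree(ped, ids, y, X, vc, rel,
                                              exog_names=["intercept", "dosage"],
                                              a_inv=a_inv)
        res = model.fit()
        chisq, df, p = res.wald_test(1)
        b = float(res.params[1])
        ve = variance_explained(maf, b, vc.var_p) if 0.0 < maf < 1.0 else 0.0
        results.append(AssociationResult(
            snp_id=sid, effect=b, se=float(res.bse[1]), wald_chisq=chisq,
            df=df, p_raw=p, p_threshold=threshold,
            significant=p < threshold, var_explained=ve))
    return results


# ---------------------------------------------------------------------------
# genotype-class least-squares means
# ---------------------------------------------------------------------------

@dataclass
class GenotypeClassLsm:
    """Per-genotype-class estimable means with pairwise-comparison letters."""

    snp_id: str
    table: pd.DataFrame  # columns: genotype, n, lsm, se, letters_05, letters_01
    pairwise: pd.DataFrame  # columns: class_a, class_b, diff, se, z, p


def genotype_class_lsm(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                       ped: Pedigree, vc: VarianceComponents, trait: str,
                       snp: int, snp_map: SnpMap | None = None,
                       a_inv: np.ndarray | None = None) -> GenotypeClassLsm:
    """Refit the mixed model with genotype as a class effect (cell means).

    Each observed class's mean and SE come straight from the fixed-effect
    solutions; all pairwise Wald z-tests are reported with superscript
    letter groupings at the 0.05 (lowercase) and 0.01 (uppercase) levels.
    Classes with fewer than 2 individuals keep their estimate and SE but
    are excluded from the letter display.
    """
    sid = snp_map.snp_id[snp] if snp_map is not None else f"snp{snp}"
    phen = phenotypes.for_trait(trait)
    ids, y, rel, gidx = _aligned_data(genotypes, phen, snp=snp)
    x = genotypes.codes[gidx, snp]
    classes = sorted(np.unique(x))
    if len(classes) < 2:
        raise ValueError(f"SNP {sid}: fewer than 2 genotype classes observed")
    X = np.column_stack([(x == c).astype(float) for c in classes])
    if a_inv is None:
        a_inv = inverse_relationship_matrix(ped)
    model = PedigreeMixedLM.from_pedigree(
        ped, ids, y, X, vc, rel,
        exog_names=[f"class{c}" for c in classes], a_inv=a_inv)
    res = model.fit()
    counts = {c: int(np.sum(x == c)) for c in classes}

    pair_rows = []
    pvals = {}
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            diff = res.params[a] - res.params[b]
            var = (res.cov_params_[a, a] + res.cov_params_[b, b]
                   - 2 * res.cov_params_[a, b])
            se = np.sqrt(max(var, 0.0))
            z = diff / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            pair_rows.append({"class_a": classes[a], "class_b": classes[b],
                              "diff": diff, "se": se, "z": z, "p": p})
            pvals[(classes[a], classes[b])] = p
    lettered = [c for c in classes if counts[c] >= 2]
    excluded = [c for c in classes if counts[c] < 2]
    if excluded:
        logger.warning("SNP %s: classes %s have < 2 individuals; "
                       "excluded from letter groupings", sid, excluded)
    means = {c: res.params[k] for k, c in enumerate(classes)}
    letters05 = _letter_groups(lettered, means, pvals, 0.05, "abcdefg")
    letters01 = _letter_groups(lettered, means, pvals, 0.01, "ABCDEFG")

    table = pd.DataFrame({
        "genotype": classes,
        "n": [counts[c] for c in classes],
        "lsm": [means[c] for c in classes],
        "se": res.bse,
        "letters_05": [letters05.get(c, "") for c in classes],
        "letters_01": [letters01.get(c, "") for c in classes],
    })
    return GenotypeClassLsm(snp_id=sid, table=table,
                            pairwise=pd.DataFrame(pair_rows))


def _letter_groups(classes, means, pvals, alpha, alphabet) -> dict:
    """Greedy compact-letter display: classes sorted by mean share a letter
    when no pair within the letter group differs at ``alpha``."""
    order = sorted(classes, key=lambda c: -means[c])
    groups: list[list] = []
    for c in order:
        placed = False
        for g in groups:
            if all(_pair_p(pvals, c, other) >= alpha for other in g):
                g.append(c)
                placed = True
        if not placed:
            groups.append([c])
    out = {c: "" for c in classes}
    for letter, g in zip(alphabet, groups):
        for c in g:
            out[c] += letter
    return out


def _pair_p(pvals, a, b) -> float:
    p = pvals.get((a, b), pvals.get((b, a), np.nan))
    return p if np.isfinite(p) else 1.0


# ---------------------------------------------------------------------------
# haplotype trend regression
# ---------------------------------------------------------------------------

@dataclass
class HtrDesign:
    """Expected-haplotype-dosage design for one block (rows sum to 2)."""

    ids: list[str]
    matrix: np.ndarray          # n x k expected dosages
    labels: list[str]           # haplotype strings, "pooled" last if present
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 2:
            raise ValueError("haplotype trend regression needs k >= 2 haplotypes")
        rows = self.matrix.sum(axis=1)
        if np.any(np.abs(rows - 2.0) > 1e-9):
            raise ValueError("each design row must sum to 2")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BlockAssociationResult:
    """Joint haplotype-block association test outcome."""

    block_id: str
    labels: list[str]            # non-reference haplotypes, in design order
    reference: str
    effects: np.ndarray          # k-1 haplotype effects vs reference
    wald_chisq: float
    df: int
    p_raw: float
    p_threshold: float
    significant: bool


def htr_design_matrix(hs: HaplotypeSet, ids: list[str]) -> HtrDesign:
    """Expected haplotype dosages for the retained (post-pooling) haplotypes."""
    return HtrDesign(ids=list(ids), matrix=hs.dosages.copy(),
                     labels=list(hs.haplotypes),
                     frequencies=np.asarray(hs.frequencies, dtype=float))


def block_association_test(design: HtrDesign, phenotypes: PhenotypeTable,
                           ped: Pedigree, vc: VarianceComponents, trait: str,
                           block_id: str = "block", alpha: float = 0.05,
                           n_blocks: int = 1,
                           a_inv: np.ndarray | None = None,
                           reference: str | None = None) -> BlockAssociationResult:
    """Mixed-model haplotype trend regression with a joint Wald test.

    The most frequent haplotype's column is dropped as the reference (the
    row-sum constraint makes all k columns plus the intercept collinear);
    the remaining k-1 effects are tested jointly, chisq = h' Var(h)^-1 h on
    k-1 df.  Bonferroni significance is judged at alpha / n_blocks.
    """
    phen = phenotypes.for_trait(trait)
    pos = {iid: k for k, iid in enumerate(design.ids)}
    pid = phen["id"].astype(str).to_numpy()
    didx = np.array([pos.get(i, -1) for i in pid], dtype=int)
    keep = didx >= 0
    ids = [i for i, k in zip(pid, keep) if k]
    y = phen["ebv"].to_numpy(dtype=float)[keep]
    rel = phen["reliability"].to_numpy(dtype=float)[keep]
    M = design.matrix[didx[keep]]
    ref_idx = (int(np.argmax(design.frequencies)) if reference is None
               else design.labels.index(reference))
    keep = [k for k in range(design.k) if k != ref_idx]
    labels = [design.labels[k] for k in keep]
    X = np.column_stack([np.ones(len(y))] + [M[:, k] for k in keep])
    if a_inv is None:
        a_inv = inverse_relationship_matrix(ped)
    try:
        model = PedigreeMixedLM.from_pedigree(
            ped, ids, y, X, vc, rel,
            exog_names=["intercept"] + labels, a_inv=a_inv)
    except ValueError as e:
        raise ValueError(f"{block_id}: collinear haplotype dosage columns "
                         f"({', '.join(labels)})") from e
    res = model.fit()
    idx = list(range(1, X.shape[1]))
    chisq, df, p = res.wald_test(idx)
    threshold = bonferroni_threshold(alpha, n_blocks)
    return BlockAssociationResult(
        block_id=block_id, labels=labels, reference=design.labels[ref_idx],
        effects=res.params[1:], wald_chisq=chisq, df=df, p_raw=p,
        p_threshold=threshold, significant=p < threshold)
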