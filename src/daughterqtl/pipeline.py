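"""End-to-end orchestration: summary statistics -> HWE screen -> single-SNP
mixed-model scan -> EM phasing -> LD + block detection -> rare-haplotype
pooling -> block trend regression -> optional expression comparison.

Outputs are a pure function of (inputs, config, seed): every stochastic
stage draws from a substream spawned off the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (block_association_test, htr_design_matrix,
                          single_snp_scan)
from .expression import genotype_expression_test, read_expression_table
from .io import (GenotypeMatrix, Pedigree, PhenotypeTable, SnpMap,
                 read_genotypes, read_pedigree, read_phenotypes, write_results)
from .kinship import inverse_relationship_matrix
from .ld import all_pairwise_ld, detect_blocks, em_haplotype_frequencies, pool_rare_haplotypes
from .mixed_model import VarianceComponents
from .popgen import summary_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, variance components and thresholds for one full run."""

    pedigree: str
    genotypes: str
    snp_map: str | None
    phenotypes: str
    out_dir: str
    variance_components: dict[str, dict[str, float]]  # trait -> var_a/var_e/var_p
    traits: list[str] | None = None
    genotype_format: str = "tabular"
    alpha: float = 0.05
    pool_threshold: float = 0.05
    em_restarts: int = 5
    em_tol: float = 1e-8
    ci_coverage: float = 0.95
    block_thresholds: tuple[float, float, float, float] = (0.70, 0.98, 0.90, 0.95)
    expression_table: str | None = None
    expression_compare: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("pedigree", "genotypes", "phenotypes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "block_thresholds" in raw:
            raw["block_thresholds"] = tuple(raw["block_thresholds"])
        if "expression_compare" in raw:
            raw["expression_compare"] = tuple(raw["expression_compare"])
        return cls(**raw)

    def vc_for(self, trait: str) -> VarianceComponents:
        d = self.variance_components.get(trait)
        if d is None:
            raise KeyError(f"no variance components configured for trait {trait!r}")
        return VarianceComponents(var_a=float(d["var_a"]), var_e=float(d["var_e"]),
                                  var_p=float(d.get("var_p") or 0) or None)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    Any stage failure raises with the stage name attached; files written
    before the failure remain on disk and are listed as partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    written: list[str] = []
    stage = "load-inputs"
    try:
        ped = read_pedigree(config.pedigree)
        gm, smap = read_genotypes(config.genotypes, format=config.genotype_format,
                                  map_path=config.snp_map)
        phen = read_phenotypes(config.phenotypes, pedigree=ped)
        traits = config.traits or phen.traits

        stage = "snp-summary"
        tab2 = summary_table(gm, smap)
        tab2.to_csv(out / "snp_summary.tsv", sep="\t", index=False)
        written.append("snp_summary.tsv")
        summary["stages"]["snp_summary"] = {
            "n_snps": int(len(tab2)),
            "hwe_failures": [str(r.snp_id) for r in tab2.itertuples()
                             if r.hwe_p < config.alpha / len(tab2)]}

        stage = "kinship"
        a_inv = inverse_relationship_matrix(ped)

        stage = "single-snp-scan"
        scan_summary = {}
        for trait in traits:
            vc = config.vc_for(trait)
            logger.info("trait %s: lambda = %.4g", trait, vc.lambda_)
            res = single_snp_scan(gm, phen, ped, vc, trait, snp_map=smap,
                                  alpha=config.alpha, a_inv=a_inv)
            write_results(res, out / f"assoc_single_{trait}.tsv")
            written.append(f"assoc_single_{trait}.tsv")
            scan_summary[trait] = {
                "significant": [r.snp_id for r in res if r.significant],
                "lambda": vc.lambda_}
        summary["stages"]["single_snp_scan"] = scan_summary

        stage = "ld-and-blocks"
        ld = all_pairwise_ld(gm, coverage=config.ci_coverage, seed=config.seed)
        ld_rows = [{"snp_i": smap.snp_id[k[0]], "snp_j": smap.snp_id[k[1]],
                    "dprime": r.dprime, "r2": r.r2,
                    "ci_low": r.ci_low, "ci_high": r.ci_high}
                   for k, r in sorted(ld.items())]
        pd.DataFrame(ld_rows).to_csv(out / "ld_pairwise.tsv", sep="\t", index=False)
        written.append("ld_pairwise.tsv")
        sl, sh, rh, frac = config.block_thresholds
        blocks = detect_blocks(ld, smap, strong_low=sl, strong_high=sh,
                               recomb_high=rh, min_strong_fraction=frac)
        block_rows = [{"block": f"block{k + 1}",
                       "chromosome": smap.chromosome[a],
                       "start": int(smap.position[a]), "end": int(smap.position[b]),
                       "first_snp": smap.snp_id[a], "last_snp": smap.snp_id[b],
                       "n_snps": b - a + 1}
                      for k, (a, b) in enumerate(blocks.blocks)]
        pd.DataFrame(block_rows, columns=["block", "chromosome", "start", "end",
                                          "first_snp", "last_snp", "n_snps"]
                     ).to_csv(out / "blocks.tsv", sep="\t", index=False)
        written.append("blocks.tsv")
        summary["stages"]["blocks"] = [(int(a), int(b)) for a, b in blocks.blocks]

        stage = "haplotype-association"
        hap_rows = []
        hap_summary = {}
        for k, (a, b) in enumerate(blocks.blocks):
            bid = f"block{k + 1}"
            hs = em_haplotype_frequencies(gm, range(a, b + 1),
                                          tol=config.em_tol,
                                          n_restarts=config.em_restarts,
                                          seed=config.seed, snp_map=smap)
            pooled = pool_rare_haplotypes(hs, config.pool_threshold)
            design = htr_design_matrix(pooled, gm.ids)
            block_p = {}
            for trait in traits:
                vc = config.vc_for(trait)
                r = block_association_test(design, phen, ped, vc, trait,
                                           block_id=bid, alpha=config.alpha,
                                           n_blocks=max(len(blocks), 1),
                                           a_inv=a_inv)
                block_p[trait] = r.p_raw
            for h, f in zip(pooled.haplotypes, pooled.frequencies):
                row = {"block": bid, "haplotype": h, "frequency": round(float(f), 4)}
                row.update({f"p_{t}": block_p[t] for t in traits})
                hap_rows.append(row)
            hap_summary[bid] = block_p
        if hap_rows:
            pd.DataFrame(hap_rows).to_csv(out / "assoc_haplotype.tsv",
                                          sep="\t", index=False)
            written.append("assoc_haplotype.tsv")
        summary["stages"]["haplotype_association"] = hap_summary

        if config.expression_table and config.expression_compare:
            stage = "expression"
            expr = read_expression_table(config.expression_table)
            ga, gb = config.expression_compare
            fold, t, p = genotype_expression_test(expr, ga, gb)
            summary["stages"]["expression"] = {
                "groups": [ga, gb], "fold_change": fold, "t": t, "p": p}
    except Exception as e:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {e}; "
            f"partial outputs: {written or 'none'}") from e

    summary["outputs"] = written
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
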