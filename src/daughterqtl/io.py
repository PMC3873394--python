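"""Readers, writers and validated on-disk artifact types.

All tabular artifacts are plain text (CSV/TSV); genotypes are accepted
either as an allele-pair table plus a MAP-like SNP description file, or as
a minimal biallelic VCF (GT field only). Genotype codes count copies of the
*minor* allele, determined from the observed sample, so a code of 2 always
means "homozygous for the rarer allele".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call, distinct from dosage 0.
MISSING: int = -1

#: Parent code meaning "unknown" in pedigree files.
UNKNOWN: str = "0"

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class PedigreeError(ValueError):
    """A pedigree violates a structural invariant (cycle, duplicate id)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Individual/sire/dam triplets in topological order (parents first).

    ``sire_idx``/``dam_idx`` hold positional indices into ``ids`` with -1
    for an unknown parent.  Individuals referenced only as parents are
    inserted as founders during construction, so sires in a daughter design
    need not have their own rows.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, str]]) -> "Pedigree":
        seen: dict[str, tuple[str, str]] = {}
        for ind, sire, dam in records:
            ind, sire, dam = str(ind), _norm_parent(sire), _norm_parent(dam)
            if ind in seen:
                raise PedigreeError(f"duplicate individual id: {ind!r}")
            if ind == UNKNOWN:
                raise PedigreeError("individual id '0' collides with the unknown-parent code")
            seen[ind] = (sire, dam)
        # implicit founders: parents never listed as individuals
        for sire, dam in list(seen.values()):
            for p in (sire, dam):
                if p != UNKNOWN and p not in seen:
                    seen[p] = (UNKNOWN, UNKNOWN)
        order = _topological_order(seen)
        pos = {iid: k for k, iid in enumerate(order)}
        sire_idx = np.array([pos[seen[i][0]] if seen[i][0] != UNKNOWN else -1 for i in order])
        dam_idx = np.array([pos[seen[i][1]] if seen[i][1] != UNKNOWN else -1 for i in order])
        return cls(ids=order, sire_idx=sire_idx, dam_idx=dam_idx)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    def records(self) -> list[tuple[str, str, str]]:
        out = []
        for k, iid in enumerate(self.ids):
            s = self.ids[self.sire_idx[k]] if self.sire_idx[k] >= 0 else UNKNOWN
            d = self.ids[self.dam_idx[k]] if self.dam_idx[k] >= 0 else UNKNOWN
            out.append((iid, s, d))
        return out

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} not in pedigree") from None


def _norm_parent(p: object) -> str:
    p = "" if p is None else str(p).strip()
    return UNKNOWN if p in ("", UNKNOWN, "NA", "na", ".") else p


def _topological_order(ped: dict[str, tuple[str, str]]) -> list[str]:
    """Kahn's algorithm over the parent->offspring DAG; detects cycles."""
    children: dict[str, list[str]] = {i: [] for i in ped}
    indeg = {i: 0 for i in ped}
    for ind, (s, d) in ped.items():
        for p in (s, d):
            if p != UNKNOWN:
                children[p].append(ind)
                indeg[ind] += 1
    queue = sorted(i for i, k in indeg.items() if k == 0)
    order: list[str] = []
    while queue:
        nxt = queue.pop(0)
        order.append(nxt)
        for c in children[nxt]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(ped):
        bad = sorted(i for i, k in indeg.items() if k > 0)[0]
        raise PedigreeError(f"pedigree cycle detected involving individual {bad!r}")
    return order


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column individual/sire/dam table (CSV/TSV, optional header)."""
    df = _read_table(path, min_cols=3)
    if _looks_like_header(df.iloc[0], {"id", "individual", "animal", "sire", "dam",
                                       "father", "mother", "sire_id", "dam_id"}):
        df = df.iloc[1:]
    if df.shape[1] < 3:
        raise FormatError(f"{path}: pedigree file needs 3 columns (individual, sire, dam)")
    recs = [(r.iloc[0], r.iloc[1], r.iloc[2]) for _, r in df.iterrows()]
    return Pedigree.from_records(recs)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame(ped.records(), columns=["individual", "sire", "dam"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP map & genotypes
# ---------------------------------------------------------------------------

@dataclass
class SnpMap:
    """Per-SNP metadata: id, chromosome, 1-based position, alleles.

    ``minor_allele`` is filled in from the genotype data (observed sample
    frequency; ties at 0.5 broken toward the alt allele).
    """

    snp_id: list[str]
    chromosome: list[str]
    position: np.ndarray  # int, 1-based bp
    ref_allele: list[str]
    alt_allele: list[str]
    minor_allele: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)
        for r, a in zip(self.ref_allele, self.alt_allele):
            if r not in _VALID_BASES or a not in _VALID_BASES:
                raise FormatError(f"allele not in A/C/G/T: {r!r}/{a!r}")
            if r == a:
                raise FormatError(f"ref and alt alleles identical: {r!r}")
        by_chrom: dict[str, int] = {}
        for c, p in zip(self.chromosome, self.position):
            if c in by_chrom and p <= by_chrom[c]:
                raise FormatError(
                    f"SNP positions must be strictly increasing within chromosome {c}")
            by_chrom[c] = p

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        d = {"snp_id": self.snp_id, "chromosome": self.chromosome,
             "position": self.position, "ref_allele": self.ref_allele,
             "alt_allele": self.alt_allele}
        if self.minor_allele:
            d["minor_allele"] = self.minor_allele
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage codes, individuals x SNPs, with MISSING = -1."""

    ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise FormatError("genotype code matrix shape does not match id list")
        ok = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not ok.all():
            raise FormatError("genotype codes must be in {0,1,2} or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]


def read_snp_map(path: str | Path) -> SnpMap:
    """Read a MAP-like file: snp_id, chromosome, position, ref, alt."""
    df = _read_table(path, min_cols=5)
    if _looks_like_header(df.iloc[0], {"snp_id", "snp", "chrom", "chromosome",
                                       "position", "pos", "ref", "alt",
                                       "ref_allele", "alt_allele"}):
        df = df.iloc[1:]
    return SnpMap(
        snp_id=[str(x) for x in df.iloc[:, 0]],
        chromosome=[str(x) for x in df.iloc[:, 1]],
        position=df.iloc[:, 2].astype(int).to_numpy(),
        ref_allele=[str(x).upper() for x in df.iloc[:, 3]],
        alt_allele=[str(x).upper() for x in df.iloc[:, 4]],
    )


def read_genotypes(path: str | Path, format: str = "tabular",
                   snp_map: SnpMap | None = None,
                   map_path: str | Path | None = None,
                   ) -> tuple[GenotypeMatrix, SnpMap]:
    """Read genotypes and return minor-allele dosage codes plus the map.

    ``tabular`` expects one row per individual (first column the id) and one
    allele-pair column per SNP ("TG", "--" for missing), with the SNP order
    given by ``snp_map``/``map_path``.  ``vcf`` reads biallelic SNP records
    with a GT field from an uncompressed or bgzipped VCF.
    """
    if format == "tabular":
        if snp_map is None:
            if map_path is None:
                raise ValueError("tabular genotypes need snp_map or map_path")
            snp_map = read_snp_map(map_path)
        return _read_tabular_genotypes(path, snp_map)
    if format == "vcf":
        return _read_vcf_genotypes(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tabular_genotypes(path, snp_map: SnpMap) -> tuple[GenotypeMatrix, SnpMap]:
    df = _read_table(path, min_cols=1 + len(snp_map))
    if _looks_like_header(df.iloc[0], set(snp_map.snp_id) | {"id", "individual"}):
        df = df.iloc[1:]
    if df.shape[1] != 1 + len(snp_map):
        raise FormatError(
            f"{path}: expected {1 + len(snp_map)} columns (id + one per SNP), "
            f"found {df.shape[1]}")
    ids = [str(x) for x in df.iloc[:, 0]]
    n, m = len(ids), len(snp_map)
    # allele counts per SNP keyed by (ref, alt)
    codes_alt = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        ref, alt = snp_map.ref_allele[j], snp_map.alt_allele[j]
        for i, cell in enumerate(df.iloc[:, j + 1]):
            cell = str(cell).strip().upper()
            if cell in ("--", "..", "NN", "", "NAN", "./."):
                continue
            if len(cell) != 2:
                raise FormatError(f"bad genotype string {cell!r} for SNP "
                                  f"{snp_map.snp_id[j]}")
            cnt = 0
            for ch in cell:
                if ch == alt:
                    cnt += 1
                elif ch != ref:
                    if ch not in _VALID_BASES:
                        raise FormatError(f"allele {ch!r} not in A/C/G/T at SNP "
                                          f"{snp_map.snp_id[j]}")
                    raise FormatError(
                        f"third allele {ch!r} observed at SNP {snp_map.snp_id[j]} "
                        f"(expected {ref}/{alt})")
            codes_alt[i, j] = cnt
    return _orient_to_minor(ids, codes_alt, snp_map)


def _read_vcf_genotypes(path) -> tuple[GenotypeMatrix, SnpMap]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_id, chrom, pos, ref_a, alt_a, rows = [], [], [], [], [], []
    for rec in vcf:
        alts = rec.ALT
        if (len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1
                or rec.REF not in _VALID_BASES or alts[0] not in _VALID_BASES):
            logger.warning("skipping non-biallelic-SNP record at %s:%s",
                           rec.CHROM, rec.POS)
            continue
        snp_id.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref_a.append(rec.REF)
        alt_a.append(alts[0])
        gts = rec.genotype.array()[:, :2]  # two allele columns
        alt_count = np.where((gts < 0).any(axis=1), MISSING,
                             gts.clip(min=0).sum(axis=1)).astype(np.int8)
        rows.append(alt_count)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic SNP records")
    codes_alt = np.stack(rows, axis=1)
    smap = SnpMap(snp_id=snp_id, chromosome=chrom, position=np.array(pos),
                  ref_allele=ref_a, alt_allele=alt_a)
    return _orient_to_minor(ids, codes_alt, smap)


def _orient_to_minor(ids, codes_alt, snp_map: SnpMap) -> tuple[GenotypeMatrix, SnpMap]:
    """Flip alt-allele counts to minor-allele counts per SNP.

    Minor allele comes from the observed sample frequency; a tie (frequency
    exactly 0.5) keeps the alt allele as minor.
    """
    codes = codes_alt.copy()
    minor: list[str] = []
    for j in range(codes.shape[1]):
        col = codes_alt[:, j]
        obs = col[col != MISSING]
        alt_freq = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
        if alt_freq > 0.5:
            minor.append(snp_map.ref_allele[j])
            codes[:, j] = np.where(col == MISSING, MISSING, 2 - col)
        else:
            minor.append(snp_map.alt_allele[j])
    smap = SnpMap(snp_id=list(snp_map.snp_id), chromosome=list(snp_map.chromosome),
                  position=snp_map.position.copy(), ref_allele=list(snp_map.ref_allele),
                  alt_allele=list(snp_map.alt_allele), minor_allele=minor)
    return GenotypeMatrix(ids=ids, codes=codes), smap


def write_tabular_genotypes(gm: GenotypeMatrix, snp_map: SnpMap,
                            path: str | Path) -> None:
    """Write the allele-pair tabular dialect (inverse of the tabular reader)."""
    rows = []
    for i, iid in enumerate(gm.ids):
        row = [iid]
        for j in range(gm.n_snps):
            c = gm.codes[i, j]
            minor = snp_map.minor_allele[j] if snp_map.minor_allele else snp_map.alt_allele[j]
            major = (snp_map.ref_allele[j] if minor == snp_map.alt_allele[j]
                     else snp_map.alt_allele[j])
            row.append("--" if c == MISSING else major * (2 - c) + minor * c)
        rows.append(row)
    pd.DataFrame(rows, columns=["id"] + list(snp_map.snp_id)).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-individual EBV and reliability for one or more traits."""

    data: pd.DataFrame  # columns: id, trait, ebv, reliability

    def __post_init__(self) -> None:
        need = {"id", "trait", "ebv", "reliability"}
        if not need.issubset(self.data.columns):
            raise FormatError(f"phenotype table needs columns {sorted(need)}")
        rel = self.data["reliability"].to_numpy(dtype=float)
        if np.any(rel <= 0) or np.any(rel > 1):
            raise FormatError("reliability must lie in (0, 1]")
        if self.data.duplicated(["id", "trait"]).any():
            raise FormatError("duplicate (id, trait) phenotype rows")

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["id"].astype(str)))

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.reset_index(drop=True)

    def cross_check(self, ped: Pedigree) -> None:
        known = set(ped.ids)
        bad = sorted(set(self.data["id"].astype(str)) - known)
        if bad:
            raise FormatError(f"phenotyped individuals missing from pedigree: {bad[:5]}")


def read_phenotypes(path: str | Path, pedigree: Pedigree | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    df.columns = [str(c).lower() for c in df.columns]
    tbl = PhenotypeTable(df.astype({"id": str, "trait": str,
                                    "ebv": float, "reliability": float}))
    if pedigree is not None:
        tbl.cross_check(pedigree)
    return tbl


def write_phenotypes(tbl: PhenotypeTable, path: str | Path) -> None:
    tbl.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Single-locus (or single-block) association test outcome."""

    snp_id: str
    effect: float           # allele-substitution estimate, trait units/copy
    se: float
    wald_chisq: float
    df: int
    p_raw: float
    p_threshold: float
    significant: bool
    var_explained: float

    _COLUMNS = ("snp", "effect", "se", "wald_chisq", "df", "p_raw",
                "p_threshold", "significant", "var_explained")

    def as_row(self) -> list:
        return [self.snp_id, self.effect, self.se, self.wald_chisq, self.df,
                self.p_raw, self.p_threshold, self.significant, self.var_explained]


def write_results(results: Sequence[AssociationResult], path: str | Path) -> None:
    """Write association results as TSV at 12 significant digits."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(AssociationResult._COLUMNS) + "\n")
        for r in results:
            cells = []
            for v in r.as_row():
                if isinstance(v, bool):
                    cells.append("TRUE" if v else "FALSE")
                elif isinstance(v, float):
                    cells.append(f"{v:.12g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results(path: str | Path) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(AssociationResult(
            snp_id=str(r["snp"]), effect=float(r["effect"]), se=float(r["se"]),
            wald_chisq=float(r["wald_chisq"]), df=int(r["df"]),
            p_raw=float(r["p_raw"]), p_threshold=float(r["p_threshold"]),
            significant=str(r["significant"]).upper() == "TRUE",
            var_explained=float(r["var_explained"])))
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, min_cols: int = 1) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty file")
    sep = "," if ("," in text.splitlines()[0]) else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str,
                     engine="python", comment="#")
    return df


def _looks_like_header(row: pd.Series, known: set[str]) -> bool:
    vals = {str(v).strip().lower() for v in row}
    return bool(vals & {k.lower() for k in known})
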