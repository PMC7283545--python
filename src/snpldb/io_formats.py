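"""Canonical in-memory data model and readers/writers for external formats.

The pipeline works on inbred (selfing) germplasm accessions, so genotypes are
effectively homozygous: a cell of the genotype matrix is one of four integer
codes (0 = homozygous reference, 1 = homozygous alternate, 2 = heterozygous,
-1 = missing).  Heterozygous calls survive I/O untouched and are only resolved
during QC.  All genomic coordinates are 1-based and inclusive, matching the
VCF and GFF3 conventions of the input files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies

POPULATIONS = ("WA", "LR", "RC")  # annual wild -> landrace -> released cultivar
ECOREGIONS = ("I", "II", "III", "IV")  # Chinese soybean cropping ecoregions
SUBPOPULATIONS = tuple(f"{p}_{e}" for p in POPULATIONS for e in ECOREGIONS)

CODE_MISSING = -1
CODE_REF = 0
CODE_ALT = 1
CODE_HET = 2

_GT_TO_CODE = {"0/0": 0, "1/1": 1, "0/1": 2, "1/0": 2, "./.": -1}
_CODE_TO_GT = {0: "0/0", 1: "1/1", 2: "0/1", -1: "./."}


class VcfFormatError(ValueError):
    """Raised when a VCF violates the biallelic diploid GT contract."""


# ---------------------------------------------------------------------------
# Core containers


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs genotype codes with per-SNP genomic metadata.

    ``codes[i, j]`` is the genotype of accession ``i`` at SNP ``j`` using the
    module-level integer coding.  Positions must be strictly increasing within
    each chromosome.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # per-SNP chromosome name (str)
    pos: np.ndarray  # per-SNP 1-based position (int)
    codes: np.ndarray  # int8, shape (n_accessions, n_snps)
    ref: np.ndarray | None = None  # per-SNP reference base
    alt: np.ndarray | None = None  # per-SNP alternate base

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.ref is not None:
            self.ref = np.asarray(self.ref, dtype=object)
        if self.alt is not None:
            self.alt = np.asarray(self.alt, dtype=object)
        n_acc, n_snp = self.codes.shape
        if n_acc != len(self.accession_ids) or n_snp != len(self.snp_ids):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.snp_ids)} SNPs"
            )
        if len(self.chrom) != n_snp or len(self.pos) != n_snp:
            raise ValueError("per-SNP metadata length mismatch")
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.codes[bad])}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def take_snps(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            codes=self.codes[:, idx].copy(),
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_snps(np.arange(self.n_snps))


@dataclass
class PhenotypeTable:
    """Two-category phenotype observations, one row per accession per trait."""

    frame: pd.DataFrame  # columns: accession_id, trait, category

    def __post_init__(self) -> None:
        required = {"accession_id", "trait", "category"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        for trait, sub in self.frame.groupby("trait"):
            if sub["accession_id"].duplicated().any():
                raise ValueError(f"duplicate accession ids for trait {trait!r}")
            if sub["category"].nunique() > 2:
                raise ValueError(f"trait {trait!r} has more than two categories")

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    def categories(self, trait: str) -> list[str]:
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise KeyError(f"unknown trait: {trait}")
        return sorted(sub["category"].unique())

    def series(self, trait: str) -> pd.Series:
        """accession_id -> category for one trait."""
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise KeyError(f"unknown trait: {trait}")
        return sub.set_index("accession_id")["category"]


@dataclass
class AccessionMetadata:
    """Population (WA/LR/RC) and ecoregion (I-IV) of every accession."""

    frame: pd.DataFrame  # columns: accession_id, population, ecoregion

    def __post_init__(self) -> None:
        required = {"accession_id", "population", "ecoregion"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        bad_pop = set(self.frame["population"]) - set(POPULATIONS)
        if bad_pop:
            raise ValueError(f"unknown populations: {sorted(bad_pop)}")
        bad_eco = set(self.frame["ecoregion"]) - set(ECOREGIONS)
        if bad_eco:
            raise ValueError(f"unknown ecoregions: {sorted(bad_eco)}")
        if self.frame["accession_id"].duplicated().any():
            raise ValueError("duplicate accession ids in metadata")

    def population_of(self) -> pd.Series:
        return self.frame.set_index("accession_id")["population"]

    def subpopulation_of(self) -> pd.Series:
        s = self.frame.set_index("accession_id")
        return s["population"] + "_" + s["ecoregion"]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: 1-based closed interval plus free-text function."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    note: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic diploid VCF into a :class:`GenotypeMatrix`.

    Genotype mapping: ``0/0``->0, ``1/1``->1, ``0/1``/``1/0``->2, ``./.``->-1.
    Multiallelic records, missing GT fields, non-diploid calls and unsorted
    positions are rejected with :class:`VcfFormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    accession_ids = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    multiallelic: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1:
            multiallelic.append(f"{v.CHROM}:{v.POS}")
            continue
        if "GT" not in (v.FORMAT or []):
            raise VcfFormatError(f"record {v.CHROM}:{v.POS} has no GT field")
        row = np.empty(len(accession_ids), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            if len(g) != 3:  # [allele_a, allele_b, phased]
                raise VcfFormatError(
                    f"non-diploid call for sample {accession_ids[i]} at {v.CHROM}:{v.POS}"
                )
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row[i] = CODE_MISSING
            elif a == b:
                row[i] = CODE_REF if a == 0 else CODE_ALT
            else:
                row[i] = CODE_HET
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(row)
    vcf.close()
    if multiallelic:
        raise VcfFormatError(f"multiallelic records at: {', '.join(multiallelic)}")
    if not rows:
        raise VcfFormatError(f"no usable records in {path}")
    codes = np.column_stack(rows)
    try:
        return GenotypeMatrix(accession_ids, snp_ids, chroms, poss, codes,
                              ref=refs, alt=alts)
    except ValueError as e:
        raise VcfFormatError(str(e)) from e


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal deterministic VCF 4.2 with diploid GT calls."""
    ref = g.ref if g.ref is not None else np.full(g.n_snps, "A", dtype=object)
    alt = g.alt if g.alt is not None else np.full(g.n_snps, "T", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.accession_ids) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in g.codes[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t{ref[j]}\t{alt[j]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Parse a GFF3 and keep features of type ``gene`` only."""
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:  # gffutils raises several parse error types
        raise ValueError(f"malformed GFF3 {path}: {e}") from e
    genes = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        note = f.attributes.get("Note", [""])[0] if "Note" in f.attributes else ""
        genes.append(
            GeneAnnotation(
                gene_id=f.id,
                chrom=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand or "+",
                note=note,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Phenotype / metadata TSV


def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", dtype=str))


def write_phenotype_tsv(p: PhenotypeTable, path: str | Path) -> None:
    p.frame[["accession_id", "trait", "category"]].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> AccessionMetadata:
    return AccessionMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata_tsv(m: AccessionMetadata, path: str | Path) -> None:
    m.frame[["accession_id", "population", "ecoregion"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Packaged worked-example tables
#
# Three published summary tables for soybean pubescence colour (PC) and flower
# colour (FC) across the WA/LR/RC domestication series are shipped with the
# package: per-(sub)population phenotype percentages (table1), per-haplotype /
# per-gene-allele phenotype-conditional accession counts per population
# (table2), and per-haplotype frequencies per population and ecoregion
# subpopulation (table3).  table2 stores integer accession counts; every
# percentage in the other tables can be re-derived from them at population
# level.

SUBPOP_SIZES = {
    "WA": 182, "WA_I": 55, "WA_II": 59, "WA_III": 44, "WA_IV": 24,
    "LR": 396, "LR_I": 45, "LR_II": 110, "LR_III": 78, "LR_IV": 163,
    "RC": 446, "RC_I": 132, "RC_II": 183, "RC_III": 62, "RC_IV": 69,
    "CSGP": 1024,
}


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("snpldb") / "data" / name))


def read_fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged worked-example tables.

    Returns a dict with keys ``table1`` (phenotype % per (sub)population),
    ``table2`` (long-format phenotype-conditional counts per haplotype/allele
    and population, with the percentage as printed) and ``table3``
    (haplotype/allele frequency % per population and subpopulation, wide).
    Empty cells correspond to dashes in the published tables (zero counts).
    """
    t1 = pd.read_csv(_data_path("table1.tsv"), sep="\t")
    t2 = pd.read_csv(_data_path("table2.tsv"), sep="\t")
    t2["count"] = t2["count"].fillna(0).astype(int)
    t3 = pd.read_csv(_data_path("table3.tsv"), sep="\t")
    return {"table1": t1, "table2": t2, "table3": t3}
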