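"""Candidate genes near associated markers and gene-allele construction.

A candidate search takes every annotated gene overlapping the associated
marker's interval expanded by a flanking window (100 kb by default).  Inside
a candidate gene, each SNP is chi-square-tested for linkage with the marker
(against each member SNP pairwise by default, or against the marker's
haplotype classes), at a per-SNP significance level of 0.05.  The
significantly linked gene SNPs define the gene's alleles: each accession's
nucleotide string over those SNPs (REF/ALT letters).  Gene alleles are NOT
rare-collapsed — unlike SNPLDB haplotypes — because allele tables in
germplasm studies report alleles down to single carrier accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import chi2_from_table
from .evolution_tracing import FrequencyTable, frequency_table
from .io_formats import (
    AccessionMetadata,
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeTable,
)
from .snpldb_assembly import SNPLDBMarker


def genes_in_window(
    marker: SNPLDBMarker,
    annotations: list[GeneAnnotation],
    flank_kb: float = 100.0,
) -> list[GeneAnnotation]:
    """Genes overlapping the marker interval expanded by ``flank_kb`` kb.

    The window is the closed interval [start - flank, end + flank] on the
    marker's chromosome; overlap means any shared base (a gene ending exactly
    at the window edge is included).
    """
    flank = int(round(flank_kb * 1000))
    lo = marker.start - flank
    hi = marker.end + flank
    return [
        a
        for a in annotations
        if a.chrom == marker.chrom and a.end >= lo and a.start <= hi
    ]


@dataclass
class GeneSNPLinkage:
    """Linkage of one gene-internal SNP with the marker."""

    snp_id: str
    best_p: float
    p_values: list[float]  # per marker member SNP (pairwise mode) or [p]
    significant: bool


@dataclass
class LinkageTestResult:
    gene_id: str
    per_snp: list[GeneSNPLinkage]
    significant_snp_ids: list[str]
    no_snps: bool = False  # gene contained no genotyped SNPs


def _haploid_pair_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2 x 2 haploid allele count table for two 0/1 columns."""
    mask = ((x == 0) | (x == 1)) & ((y == 0) | (y == 1))
    x, y = x[mask], y[mask]
    t = np.zeros((2, 2), dtype=int)
    np.add.at(t, (x.astype(int), y.astype(int)), 1)
    return t


def snp_linkage_test(
    marker: SNPLDBMarker,
    gene: GeneAnnotation,
    g: GenotypeMatrix,
    alpha: float = 0.05,
    mode: str = "pairwise",
    correction: str = "none",
) -> LinkageTestResult:
    """Chi-square linkage of every gene-internal SNP with the marker.

    ``mode='pairwise'`` tests each gene SNP against each marker member SNP
    on 2 x 2 haploid allele tables and calls the gene SNP significant when
    *any* pair reaches ``alpha`` (optionally Bonferroni-corrected by the
    number of pairs with ``correction='bonferroni'``).  ``mode='haplotype'``
    tests one 2 x H table of gene-SNP allele by marker haplotype instead.
    """
    if mode not in ("pairwise", "haplotype"):
        raise ValueError(f"unknown mode: {mode}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction: {correction}")
    in_gene = np.flatnonzero(
        (g.chrom == gene.chrom) & (g.pos >= gene.start) & (g.pos <= gene.end)
    )
    if in_gene.size == 0:
        return LinkageTestResult(gene.gene_id, [], [], no_snps=True)
    marker_idx = [g.snp_index(s) for s in marker.snp_ids]
    per_snp = []
    for j in in_gene:
        if mode == "pairwise":
            ps = []
            for mj in marker_idx:
                t = _haploid_pair_table(g.codes[:, j], g.codes[:, mj])
                _, _, p = chi2_from_table(t)
                ps.append(p)
            thresh = alpha / len(ps) if correction == "bonferroni" else alpha
        else:
            x = g.codes[:, j]
            mask = (x == 0) | (x == 1)
            t = np.zeros((2, marker.n_haplotypes), dtype=int)
            np.add.at(
                t, (x[mask].astype(int), marker.assignments[mask]), 1
            )
            _, _, p = chi2_from_table(t)
            ps = [p]
            thresh = alpha
        best = min(ps)
        per_snp.append(
            GeneSNPLinkage(
                snp_id=g.snp_ids[j],
                best_p=best,
                p_values=ps,
                significant=best <= thresh,
            )
        )
    significant = [s.snp_id for s in per_snp if s.significant]
    return LinkageTestResult(gene.gene_id, per_snp, significant)


@dataclass
class GeneAlleleTable:
    """Gene alleles as nucleotide strings with population bookkeeping."""

    gene_id: str
    snp_ids: list[str]  # the significant gene SNPs, genome order
    alleles: list[str]  # nucleotide strings, descending frequency
    assignments: np.ndarray  # per-accession index into ``alleles``
    accession_ids: list[str]
    freq_table: FrequencyTable

    def __post_init__(self) -> None:
        if len(self.assignments) != len(self.accession_ids):
            raise ValueError("one allele assignment per accession required")
        L = len(self.snp_ids)
        if any(len(a) != L for a in self.alleles):
            raise ValueError("allele string length must equal number of SNPs")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def allele_series(self) -> pd.Series:
        return pd.Series(
            [self.alleles[a] for a in self.assignments],
            index=pd.Index(self.accession_ids, name="accession_id"),
        )


def build_gene_alleles(
    gene: GeneAnnotation,
    significant_snps: list[str],
    g: GenotypeMatrix,
    metadata: AccessionMetadata,
    phenotype: PhenotypeTable | None = None,
    trait: str | None = None,
) -> GeneAlleleTable:
    """Construct gene alleles over the significantly linked gene SNPs.

    Each accession's allele is its nucleotide string (REF letter for code 0,
    ALT letter for code 1) over the SNPs, in genome order.  Requires an
    imputed, het-free matrix with REF/ALT metadata.
    """
    if not significant_snps:
        raise ValueError("need at least one significant SNP")
    if g.ref is None or g.alt is None:
        raise ValueError("genotype matrix lacks REF/ALT nucleotides")
    idx = sorted(
        (g.snp_index(s) for s in significant_snps), key=lambda j: g.pos[j]
    )
    sub = g.codes[:, idx]
    if np.any(sub == -1) or np.any(sub == 2):
        raise ValueError("residual missing/heterozygous codes; run QC first")
    letters = np.where(
        sub == 0,
        np.broadcast_to(g.ref[idx], sub.shape),
        np.broadcast_to(g.alt[idx], sub.shape),
    )
    strings = np.array(["".join(row) for row in letters], dtype=object)
    uniq, counts = np.unique(strings, return_counts=True)
    order = np.lexsort((uniq, -counts))
    alleles = [str(uniq[i]) for i in order]
    lookup = {a: i for i, a in enumerate(alleles)}
    assignments = np.array([lookup[s] for s in strings], dtype=int)
    series = pd.Series(
        strings, index=pd.Index(g.accession_ids, name="accession_id")
    )
    ft = frequency_table(
        series, metadata, phenotype=phenotype, trait=trait, locus=gene.gene_id
    )
    return GeneAlleleTable(
        gene_id=gene.gene_id,
        snp_ids=[g.snp_ids[j] for j in idx],
        alleles=alleles,
        assignments=assignments,
        accession_ids=list(g.accession_ids),
        freq_table=ft,
    )


def rank_genes_by_linkage(
    marker: SNPLDBMarker,
    genes: list[GeneAnnotation],
    g: GenotypeMatrix,
    alpha: float = 0.05,
    mode: str = "pairwise",
) -> list[tuple[GeneAnnotation, LinkageTestResult]]:
    """Candidate genes ordered by their strongest gene-SNP linkage p."""
    scored = []
    for gene in genes:
        res = snp_linkage_test(marker, gene, g, alpha=alpha, mode=mode)
        best = min((s.best_p for s in res.per_snp), default=1.0)
        scored.append((best, gene, res))
    scored.sort(key=lambda t: (t[0], t[1].gene_id))
    return [(gene, res) for _, gene, res in scored]
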