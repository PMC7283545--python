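"""Build multi-allelic haplotype-block markers (SNPLDBs) from SNP genotypes.

Tightly linked SNPs (pairwise normalized linkage disequilibrium D' above a
threshold, 0.70 by default) are grouped left-to-right into blocks; a SNP that
cannot join its neighbours becomes a single-SNP block.  The distinct local
haplotypes over a block's member SNPs are the alleles of the resulting
marker.  Haplotypes rarer than a frequency floor (1% by default) are merged
into the closest frequent haplotype — minimal Hamming distance, highest
frequency breaking ties — so every surviving allele is common enough to test.

All LD computation is haploid: accessions are inbred, so after QC each
carries one haplotype and D' comes straight from accession counts, no EM
phasing over diploid genotypes is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


class MonomorphicSNPError(ValueError):
    """D' is undefined when one of the SNPs has a single allele."""


@dataclass(frozen=True)
class LDStatistics:
    """Pairwise linkage disequilibrium between two biallelic SNPs."""

    snp_a: str
    snp_b: str
    d: float  # coefficient of linkage disequilibrium p_AB - p_A p_B
    d_prime: float  # |D| / D_max, in [0, 1]
    p_a: float  # ref-allele frequency at snp_a
    p_b: float  # ref-allele frequency at snp_b
    n: int  # accessions with both SNPs called


@dataclass
class SNPLDBMarker:
    """A haplotype-block marker: interval, member SNPs, haplotype catalogue.

    ``haplotypes`` is ordered by descending frequency; ``assignments[i]`` is
    the catalogue index of accession ``i``'s haplotype.
    """

    marker_id: str
    chrom: str
    start: int  # position of first member SNP (1-based)
    end: int  # position of last member SNP
    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    assignments: np.ndarray
    accession_ids: list[str]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if not self.snp_ids:
            raise ValueError("marker needs at least one member SNP")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("catalogue/frequency length mismatch")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if len(self.assignments) != len(self.accession_ids):
            raise ValueError("one assignment per accession required")
        if self.assignments.min(initial=0) < 0 or (
            len(self.assignments)
            and self.assignments.max() >= len(self.haplotypes)
        ):
            raise ValueError("assignment index outside catalogue")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_series(self) -> pd.Series:
        """accession_id -> haplotype allele-string."""
        return pd.Series(
            [self.haplotypes[a] for a in self.assignments],
            index=pd.Index(self.accession_ids, name="accession_id"),
        )


def _haploid_columns(g: GenotypeMatrix, a: int, b: int):
    x = g.codes[:, a]
    y = g.codes[:, b]
    mask = ((x == 0) | (x == 1)) & ((y == 0) | (y == 1))
    return x[mask], y[mask]


def _dprime_from_counts(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(D, D', p_ref_a) from two haploid 0/1 columns of equal length."""
    n = x.size
    p_a = float((x == 0).sum()) / n  # ref allele at first SNP
    p_b = float((y == 0).sum()) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSNPError("monomorphic SNP in D' computation")
    p_ab = float(((x == 0) & (y == 0)).sum()) / n
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    else:
        return 0.0, 0.0, p_a
    return d, abs(d) / d_max, p_a


def d_prime(g: GenotypeMatrix, snp_a: int | str, snp_b: int | str) -> LDStatistics:
    """Normalized LD between two SNPs from haploid accession counts.

    Heterozygous and missing calls are excluded pairwise (the matrix is
    expected to be QC'd, where both are resolved).
    """
    a = g.snp_index(snp_a) if isinstance(snp_a, str) else snp_a
    b = g.snp_index(snp_b) if isinstance(snp_b, str) else snp_b
    x, y = _haploid_columns(g, a, b)
    if x.size == 0:
        raise MonomorphicSNPError("no jointly called accessions")
    d, dp, p_a = _dprime_from_counts(x, y)
    p_b = float((y == 0).sum()) / y.size
    return LDStatistics(g.snp_ids[a], g.snp_ids[b], d, dp, p_a, p_b, int(x.size))


def partition_blocks(
    g: GenotypeMatrix,
    threshold: float = 0.70,
    max_span_kb: float = 200.0,
) -> list[np.ndarray]:
    """Greedy left-to-right partition of SNPs into LD blocks.

    A block grows while the candidate SNP has pairwise D' above ``threshold``
    with *every* current member and the block span stays within
    ``max_span_kb``.  Monomorphic SNPs (no defined D') become singletons.
    Blocks are disjoint, genome-ordered and cover all SNPs.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    max_span = max_span_kb * 1000.0
    poly = np.array(
        [np.unique(g.codes[(g.codes[:, j] == 0) | (g.codes[:, j] == 1), j]).size == 2
         for j in range(g.n_snps)]
    )
    blocks: list[np.ndarray] = []
    for chrom in pd.unique(g.chrom):
        idx = np.flatnonzero(g.chrom == chrom)
        current: list[int] = []
        for j in idx:
            if not poly[j]:
                if current:
                    blocks.append(np.array(current))
                    current = []
                blocks.append(np.array([j]))
                continue
            if not current:
                current = [j]
                continue
            fits_span = g.pos[j] - g.pos[current[0]] <= max_span
            linked = False
            if fits_span and all(poly[m] for m in current):
                linked = True
                for m in current:
                    x, y = _haploid_columns(g, m, j)
                    if x.size == 0:
                        linked = False
                        break
                    try:
                        _, dp, _ = _dprime_from_counts(x, y)
                    except MonomorphicSNPError:
                        linked = False
                        break
                    if dp <= threshold:
                        linked = False
                        break
            if linked:
                current.append(j)
            else:
                blocks.append(np.array(current))
                current = [j]
        if current:
            blocks.append(np.array(current))
    return blocks


def call_haplotypes(
    g: GenotypeMatrix,
    block: np.ndarray | list[int],
    marker_id: str | None = None,
    min_hap_freq: float = 0.01,
    collapse: bool = True,
) -> SNPLDBMarker:
    """Turn a block of SNPs into a multi-allelic marker.

    Each accession's allele string over the member SNPs is its haplotype;
    the catalogue is ordered by descending frequency (lexicographic
    tie-break).  Rare haplotypes are merged via :func:`collapse_rare` unless
    ``collapse`` is False.  Requires an imputed, het-free matrix.
    """
    idx = np.asarray(block, dtype=int)
    sub = g.codes[:, idx]
    if np.any(sub == -1) or np.any(sub == 2):
        raise ValueError("residual missing/heterozygous codes; run QC first")
    strings = np.array(["".join(map(str, row)) for row in sub], dtype=object)
    uniq, counts = np.unique(strings, return_counts=True)
    order = np.lexsort((uniq, -counts))  # descending count, then string
    catalogue = [str(uniq[i]) for i in order]
    freq = counts[order] / strings.size
    lookup = {h: i for i, h in enumerate(catalogue)}
    assignments = np.array([lookup[s] for s in strings], dtype=int)
    chrom = str(g.chrom[idx[0]])
    marker = SNPLDBMarker(
        marker_id=marker_id or f"LDB_{chrom}_{g.pos[idx[0]]}",
        chrom=chrom,
        start=int(g.pos[idx[0]]),
        end=int(g.pos[idx[-1]]),
        snp_ids=[g.snp_ids[i] for i in idx],
        haplotypes=catalogue,
        frequencies=freq,
        assignments=assignments,
        accession_ids=list(g.accession_ids),
    )
    return collapse_rare(marker, min_hap_freq) if collapse else marker


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def collapse_rare(marker: SNPLDBMarker, min_freq: float = 0.01) -> SNPLDBMarker:
    """Merge haplotypes rarer than ``min_freq`` into an approximate haplotype.

    The target is the frequent haplotype at minimal Hamming distance from the
    rare string; among equidistant candidates the most frequent wins.  The
    merge iterates until no rare haplotype remains.  If *every* haplotype is
    rare, the two most frequent are kept and the rest collapse onto them.
    """
    n = len(marker.assignments)
    assignments = marker.assignments.copy()
    catalogue = list(marker.haplotypes)

    def counts() -> np.ndarray:
        return np.bincount(assignments, minlength=len(catalogue))

    while True:
        c = counts()
        freq = c / n
        rare = [i for i in range(len(catalogue)) if 0 < c[i] and freq[i] < min_freq]
        common = [i for i in range(len(catalogue)) if freq[i] >= min_freq]
        if not rare:
            break
        if not common:
            # Degenerate: keep the two most frequent strings as targets.
            order = sorted(range(len(catalogue)), key=lambda i: (-c[i], catalogue[i]))
            common = order[:2]
            rare = [i for i in order[2:] if c[i] > 0]
            if not rare:
                break
        for i in rare:
            best = min(
                common,
                key=lambda j: (_hamming(catalogue[i], catalogue[j]),
                               -c[j], catalogue[j]),
            )
            assignments[assignments == i] = best

    # Rebuild the catalogue without emptied haplotypes, descending frequency.
    c = counts()
    keep = [i for i in range(len(catalogue)) if c[i] > 0]
    keep.sort(key=lambda i: (-c[i], catalogue[i]))
    remap = {old: new for new, old in enumerate(keep)}
    new_assign = np.array([remap[a] for a in assignments], dtype=int)
    return replace(
        marker,
        haplotypes=[catalogue[i] for i in keep],
        frequencies=c[keep] / n,
        assignments=new_assign,
    )


def assemble_markers(
    g: GenotypeMatrix,
    threshold: float = 0.70,
    min_hap_freq: float = 0.01,
    max_span_kb: float = 200.0,
) -> list[SNPLDBMarker]:
    """Partition + haplotype calling in one pass, genome order."""
    blocks = partition_blocks(g, threshold=threshold, max_span_kb=max_span_kb)
    return [
        call_haplotypes(g, b, min_hap_freq=min_hap_freq) for b in blocks
    ]


# ---------------------------------------------------------------------------
# Serialization (marker table + accession x marker haplotype-index matrix)


def write_markers(
    markers: list[SNPLDBMarker],
    marker_path: str | Path,
    assign_path: str | Path,
) -> None:
    rows = []
    for m in markers:
        rows.append(
            {
                "marker_id": m.marker_id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "n_snps": len(m.snp_ids),
                "n_haplotypes": m.n_haplotypes,
                "snp_ids": ",".join(m.snp_ids),
                "haplotypes": ",".join(m.haplotypes),
                "frequencies": ",".join(f"{f:.10g}" for f in m.frequencies),
            }
        )
    pd.DataFrame(rows).to_csv(marker_path, sep="\t", index=False)
    assign = pd.DataFrame(
        {m.marker_id: m.assignments for m in markers},
        index=pd.Index(markers[0].accession_ids, name="accession_id"),
    )
    assign.to_csv(assign_path, sep="\t")


def read_markers(
    marker_path: str | Path, assign_path: str | Path
) -> list[SNPLDBMarker]:
    tab = pd.read_csv(marker_path, sep="\t", dtype={"chrom": str})
    assign = pd.read_csv(assign_path, sep="\t", index_col="accession_id")
    accession_ids = [str(a) for a in assign.index]
    markers = []
    for _, r in tab.iterrows():
        markers.append(
            SNPLDBMarker(
                marker_id=r["marker_id"],
                chrom=r["chrom"],
                start=int(r["start"]),
                end=int(r["end"]),
                snp_ids=r["snp_ids"].split(","),
                haplotypes=r["haplotypes"].split(","),
                frequencies=np.array([float(x) for x in r["frequencies"].split(",")]),
                assignments=assign[r["marker_id"]].to_numpy(dtype=int),
                accession_ids=accession_ids,
            )
        )
    return markers
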