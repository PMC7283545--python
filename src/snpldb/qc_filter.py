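"""SNP quality control and residual-missing-genotype imputation.

Filters follow the usual germplasm re-sequencing thresholds: a SNP is dropped
when its missing rate exceeds 20%, its heterozygous rate exceeds 20%, or its
minor allele frequency falls below 1% (all overridable; boundary values are
retained).  Rates are computed per SNP over accessions; the heterozygous rate
and MAF use non-missing calls as denominator, with a heterozygous call
contributing half to each allele.

Residual missing genotypes are imputed with a k-nearest-accession window
vote: the most frequent non-missing code among the k accessions closest in
Hamming distance over a flanking SNP window.  Because the downstream
haplotype bookkeeping treats every inbred accession as carrying a single
haplotype, residual heterozygous calls are collapsed to the per-SNP major
homozygote first (a deliberately lossy step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass(frozen=True)
class QCConfig:
    max_missing_rate: float = 0.20
    max_het_rate: float = 0.20
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "max_het_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")


class QCError(ValueError):
    """All SNPs failed QC; the per-SNP report is attached as ``.report``."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


def snp_statistics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP missing rate, heterozygous rate and minor allele frequency."""
    codes = g.codes
    n = codes.shape[0]
    missing = codes == -1
    het = codes == 2
    n_called = n - missing.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        missing_rate = missing.sum(axis=0) / n
        het_rate = np.where(n_called > 0, het.sum(axis=0) / n_called, 0.0)
        alt = (codes == 1).sum(axis=0) + 0.5 * het.sum(axis=0)
        ref = (codes == 0).sum(axis=0) + 0.5 * het.sum(axis=0)
        total = alt + ref
        p_alt = np.where(total > 0, alt / total, 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "maf": maf,
        }
    )


def filter_snps(
    g: GenotypeMatrix, qc: QCConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs violating the QC thresholds; accessions are never dropped.

    Returns the filtered matrix and a per-SNP report with the statistics and
    the first rule that removed each dropped SNP.  Raises :class:`QCError` if
    nothing survives.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    qc = qc or QCConfig()
    report = snp_statistics(g)
    reason = np.full(g.n_snps, "", dtype=object)
    reason[report["maf"].values < qc.min_maf] = "maf"
    reason[report["het_rate"].values > qc.max_het_rate] = "het_rate"
    reason[report["missing_rate"].values > qc.max_missing_rate] = "missing_rate"
    report["kept"] = reason == ""
    report["reason"] = reason
    keep_idx = np.flatnonzero(report["kept"].values)
    if keep_idx.size == 0:
        raise QCError("all SNPs removed by QC", report)
    return g.take_snps(keep_idx), report


def impute_missing(
    g: GenotypeMatrix,
    seed: int = 0,
    k: int = 10,
    window: int = 50,
) -> GenotypeMatrix:
    """Resolve heterozygous calls and impute missing genotypes.

    Heterozygous codes become the per-SNP major homozygote.  Each missing
    cell is filled with the most frequent non-missing code among the ``k``
    accessions at smallest Hamming distance over a ``window``-SNP flanking
    window (ties broken by the per-SNP major allele).  Deterministic for a
    given input; voting uses the pre-imputation matrix so the result does not
    depend on fill order.
    """
    del seed  # procedure is fully deterministic; kept for interface stability
    codes = g.codes.copy()
    n_acc, n_snps = codes.shape

    called = (codes == 0) | (codes == 1)
    n_called = called.sum(axis=0)
    if np.any((codes == -1).all(axis=0)):
        bad = [g.snp_ids[j] for j in np.flatnonzero((codes == -1).all(axis=0))]
        raise ValueError(f"SNPs with zero non-missing calls: {bad}")

    # Major homozygote per SNP among homozygous calls (ref wins ties).
    n_alt = (codes == 1).sum(axis=0)
    major = (n_alt * 2 > n_called).astype(np.int8)
    het_cells = codes == 2
    codes[het_cells] = np.broadcast_to(major, codes.shape)[het_cells]

    observed = codes != -1  # post het-resolution
    out = codes.copy()
    half = window // 2
    for j in np.flatnonzero((codes == -1).any(axis=0)):
        lo = max(0, j - half)
        hi = min(n_snps, j + half + 1)
        W = codes[:, lo:hi]
        W_obs = observed[:, lo:hi]
        donors_ok = codes[:, j] != -1
        for i in np.flatnonzero(codes[:, j] == -1):
            both = W_obs & W_obs[i]
            mism = (W != W[i]) & both
            overlap = both.sum(axis=1)
            with np.errstate(invalid="ignore"):
                dist = np.where(overlap > 0, mism.sum(axis=1) / overlap, 1.0)
            dist = np.where(donors_ok, dist, np.inf)
            dist[i] = np.inf
            order = np.argsort(dist, kind="stable")[:k]
            votes = codes[order, j]
            votes = votes[votes != -1]
            if votes.size == 0:
                out[i, j] = major[j]
                continue
            n1 = int((votes == 1).sum())
            n0 = votes.size - n1
            if n1 > n0:
                out[i, j] = 1
            elif n0 > n1:
                out[i, j] = 0
            else:
                out[i, j] = major[j]
    result = g.copy()
    result.codes = out
    return result
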