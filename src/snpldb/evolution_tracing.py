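"""Haplotype/allele frequency structure across the domestication series.

Frequencies are bookkept per population (WA -> LR -> RC) and per ecoregion
subpopulation (I north ... IV south), with phenotype-conditional counts per
population.  On top of the bookkeeping sit three small inferences used to
read domestication history off a germplasm table:

* a haplotype observed later but never among n earlier accessions is called
  *emerged* when the binomial probability of missing it by sampling error,
  (1 - f)^n with f its observed later frequency, falls below a threshold
  (1e-6 by default) — the exponent is n, not 2n, because each inbred
  accession carries a single haplotype;
* a haplotype present earlier and absent from a later population onward is
  *excluded* (by domestication or artificial selection);
* the candidate wild sources of a haplotype are the WA subpopulations
  carrying it, ordered by descending frequency with southern ecoregions
  (IV before III before II before I) breaking ties, encoding the southern
  origin of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ECOREGIONS,
    POPULATIONS,
    SUBPOPULATIONS,
    SUBPOP_SIZES,
    AccessionMetadata,
    PhenotypeTable,
    read_fixture_tables,
)

_SOUTH_FIRST = {"IV": 0, "III": 1, "II": 2, "I": 3}


@dataclass
class FrequencyTable:
    """Counts of haplotypes/alleles per subpopulation (+ phenotype splits).

    ``counts`` is labels x subpopulations; ``pheno_counts``, when available,
    is labels x (population, category) accession counts.  Counts are stored
    at full precision; percentage views round only for report output.
    """

    locus: str
    counts: pd.DataFrame
    pheno_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < -1e-9).any():
            raise ValueError("negative counts")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def subpop_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def pop_counts(self) -> pd.DataFrame:
        out = {}
        for p in POPULATIONS:
            cols = [c for c in self.counts.columns if c.startswith(p + "_")]
            out[p] = self.counts[cols].sum(axis=1)
        return pd.DataFrame(out)

    def pop_sizes(self) -> pd.Series:
        return self.pop_counts().sum(axis=0)

    def pop_freq(self) -> pd.DataFrame:
        pc = self.pop_counts()
        return pc / pc.sum(axis=0)

    def subpop_freq(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def percent_frame(self) -> pd.DataFrame:
        """Population + subpopulation frequencies in %, 1-decimal rounding."""
        freq = pd.concat([self.pop_freq(), self.subpop_freq()], axis=1)
        return (100.0 * freq).round(1)

    def pheno_percent(self) -> pd.DataFrame:
        """Phenotype share (%) within each (label, population) carrier group."""
        if self.pheno_counts is None:
            raise ValueError("no phenotype-conditional counts")
        pc = self.pheno_counts
        totals = pc.T.groupby(level=0).sum().T
        out = pc.copy().astype(float)
        for pop, cat in pc.columns:
            denom = totals[pop].replace(0, np.nan)
            out[(pop, cat)] = 100.0 * pc[(pop, cat)] / denom
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.percent_frame().to_csv(path, sep="\t")


def frequency_table(
    assignments: pd.Series,
    metadata: AccessionMetadata,
    phenotype: PhenotypeTable | None = None,
    trait: str | None = None,
    locus: str = "locus",
) -> FrequencyTable:
    """Tabulate haplotype/allele assignments by subpopulation and phenotype.

    ``assignments`` maps accession_id -> haplotype/allele label.  Labels are
    ordered by descending overall count.  Raises if any assigned accession is
    missing from the metadata.
    """
    subpop = metadata.subpopulation_of()
    missing = assignments.index.difference(subpop.index)
    if len(missing):
        raise ValueError(f"accessions without metadata: {list(missing[:5])}")
    sp = subpop.reindex(assignments.index)
    counts = (
        pd.crosstab(assignments.values, sp.values)
        .reindex(columns=list(SUBPOPULATIONS), fill_value=0)
        .fillna(0)
    )
    counts = counts.loc[
        sorted(counts.index, key=lambda h: (-counts.loc[h].sum(), str(h)))
    ]
    counts.index.name = "label"
    counts.columns.name = None

    pheno_counts = None
    if phenotype is not None:
        if trait is None:
            traits = phenotype.traits
            if len(traits) != 1:
                raise ValueError(f"specify trait; table has {traits}")
            trait = traits[0]
        cats = phenotype.series(trait).reindex(assignments.index)
        pop = metadata.population_of().reindex(assignments.index)
        pheno_counts = pd.crosstab(
            assignments.values, [pop.values, cats.values]
        )
        full_cols = pd.MultiIndex.from_product(
            [POPULATIONS, phenotype.categories(trait)]
        )
        pheno_counts = pheno_counts.reindex(
            index=counts.index, columns=full_cols, fill_value=0
        ).fillna(0).astype(int)
    return FrequencyTable(locus=locus, counts=counts, pheno_counts=pheno_counts)


def fixture_frequency_table(locus: str) -> FrequencyTable:
    """Build a FrequencyTable for one packaged worked-example locus.

    Subpopulation counts are reconstructed from the published subpopulation
    frequency percentages and subpopulation sizes (hence fractional);
    phenotype-conditional population counts come verbatim from the published
    accession counts.
    """
    tables = read_fixture_tables()
    t2 = tables["table2"]
    t3 = tables["table3"]
    rows3 = t3[t3["locus"] == locus]
    if rows3.empty:
        raise KeyError(f"unknown fixture locus: {locus}")
    counts = pd.DataFrame(
        {
            sp: rows3[sp].fillna(0).values * SUBPOP_SIZES[sp] / 100.0
            for sp in SUBPOPULATIONS
        },
        index=pd.Index(rows3["allele"].values, name="label"),
    )
    rows2 = t2[t2["locus"] == locus]
    pheno = rows2.pivot_table(
        index="allele", columns=["population", "category"], values="count",
        aggfunc="sum", fill_value=0,
    ).reindex(index=counts.index).fillna(0).astype(int)
    return FrequencyTable(locus=locus, counts=counts, pheno_counts=pheno)


def absence_probability(freq: float, n: int) -> float:
    """P(haplotype at true frequency ``freq`` unseen in n inbred accessions).

    One haplotype per accession, so the exponent is n: (1 - freq)^n,
    evaluated in log space for numerical stability.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError(f"freq must be in (0,1), got {freq}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(np.exp(n * np.log1p(-freq)))


@dataclass
class TracingResult:
    """Domestication status of one haplotype across the population series."""

    haplotype: str
    status: dict[str, str]  # population -> present/absent/emerged/excluded
    absence_probability: float | None  # for emerged haplotypes
    sources: list[str]  # candidate WA source subpopulations, best first

    def __post_init__(self) -> None:
        if self.absence_probability is not None and not (
            0.0 <= self.absence_probability <= 1.0
        ):
            raise ValueError("absence probability outside [0,1]")


def classify_haplotypes(
    ft: FrequencyTable,
    order: tuple[str, ...] = POPULATIONS,
    alpha: float = 1e-6,
) -> list[TracingResult]:
    """Label each haplotype present/absent/emerged/excluded per population.

    *Emerged in P*: zero count in every population before P, nonzero in P,
    and the binomial probability of the haplotype (at its frequency in P)
    being missed in all earlier accessions combined is below ``alpha``.
    *Excluded in P*: nonzero earlier, zero in P and in every later
    population.
    """
    if len(order) < 2:
        raise ValueError("need at least two populations to classify")
    pc = ft.pop_counts()[list(order)]
    sizes = pc.sum(axis=0)
    results = []
    for hap in ft.labels:
        row = pc.loc[hap]
        present = row.values > 1e-9
        status = {
            p: ("present" if present[i] else "absent")
            for i, p in enumerate(order)
        }
        abs_p = None
        # Emergence: first population with the haplotype, if not the first
        # population in the series and sampling error is ruled out.
        if present.any():
            first = int(np.argmax(present))
            if first > 0:
                n_earlier = int(sizes.iloc[:first].sum())
                f = row.iloc[first] / sizes.iloc[first]
                if 0.0 < f < 1.0 and n_earlier >= 1:
                    abs_p = absence_probability(f, n_earlier)
                    if abs_p < alpha:
                        status[order[first]] = "emerged"
            # Exclusion: zero tail after a nonzero population.
            for i, p in enumerate(order):
                if not present[i] and present[:i].any() and not present[i:].any():
                    status[p] = "excluded"
        try:
            sources = trace_sources(ft, hap)
        except KeyError:
            sources = []
        results.append(
            TracingResult(
                haplotype=str(hap),
                status=status,
                absence_probability=abs_p,
                sources=sources,
            )
        )
    return results


def trace_sources(ft: FrequencyTable, haplotype: str) -> list[str]:
    """WA subpopulations carrying the haplotype, most plausible source first.

    Ordered by descending frequency; equal frequencies fall back to the
    southern-first ecoregion order (IV, III, II, I).  Empty if the haplotype
    is absent from WA (it emerged later).
    """
    if haplotype not in ft.counts.index:
        raise KeyError(f"unknown haplotype id: {haplotype}")
    wa_cols = [f"WA_{e}" for e in ECOREGIONS]
    sizes = ft.counts[wa_cols].sum(axis=0)
    freqs = {}
    for col in wa_cols:
        n = sizes[col]
        c = ft.counts.loc[haplotype, col]
        if n > 0 and c > 1e-9:
            freqs[col] = c / n
    return sorted(
        freqs,
        key=lambda col: (-freqs[col], _SOUTH_FIRST[col.split("_")[1]]),
    )
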