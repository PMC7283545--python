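"""Synthetic inbred germplasm populations with known multi-allelic causal loci.

The generator emulates the data structure the downstream analysis assumes: a
selfing (effectively homozygous) collection structured into three
domestication populations (WA annual wild, LR landrace, RC released cultivar),
each split into four ecoregion subpopulations (I north ... IV south).
Chromosomes are built from discrete LD blocks; each accession carries exactly
one haplotype per block, drawn from its subpopulation's haplotype-frequency
vector.  A designated causal block determines the two-category phenotype via
per-haplotype, per-population penetrance — the probability that a carrier
expresses the derived category — so one haplotype can show both phenotypes.
Haplotype emergence (zero frequency in earlier populations) and exclusion
(zero frequency in later ones) are expressed directly through the frequency
vectors.  Missing and heterozygous codes are injected after phenotype
assignment so the QC stage has something to clean without distorting truth.

Block haplotype pools are threshold-type: allele strings are nested, like a
staircase (00000, 10000, 11000, ...) possibly with permuted columns, which
guarantees strong pairwise LD (D' = 1) inside every block — the regime the
haplotype-block marker construction is designed for.  Neutral blocks are
sized so that the imputer's SNP window is dominated by within-block signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ECOREGIONS,
    POPULATIONS,
    SUBPOPULATIONS,
    AccessionMetadata,
    GenotypeMatrix,
    PhenotypeTable,
    write_metadata_tsv,
    write_phenotype_tsv,
    write_vcf,
)

# Physical layout of simulated chromosomes (bp).
BLOCK_SPACING = 150_000  # distance between the starts of consecutive blocks
SNP_SPACING = 2_000  # distance between adjacent SNPs inside a block

#: Accession counts per subpopulation matching a representative Chinese
#: soybean germplasm sample (182 WA + 396 LR + 446 RC = 1,024).
DEFAULT_SUBPOP_SIZES = {
    "WA_I": 55, "WA_II": 59, "WA_III": 44, "WA_IV": 24,
    "LR_I": 45, "LR_II": 110, "LR_III": 78, "LR_IV": 163,
    "RC_I": 132, "RC_II": 183, "RC_III": 62, "RC_IV": 69,
}


def staircase_haplotypes(n_snps: int, k: int) -> list[str]:
    """``k`` allele strings of length ``n_snps``: 000.., 100.., 110.., ...

    Any two strings differ in a contiguous prefix, so every SNP pair shows at
    most three of the four gametes and has D' = 1 within the block.
    """
    if not 2 <= k <= n_snps + 1:
        raise ValueError(f"need 2 <= k <= n_snps+1, got k={k}, n_snps={n_snps}")
    return ["1" * i + "0" * (n_snps - i) for i in range(k)]


@dataclass
class CausalLocusSpec:
    """A causal haplotype block: frequencies per subpopulation + penetrance.

    ``frequencies`` maps a population ("WA") or subpopulation ("WA_I") name to
    a frequency vector over ``haplotypes``; a subpopulation key overrides its
    population key.  ``penetrance[hap][pop]`` is the probability that a
    carrier of ``hap`` in population ``pop`` shows the derived phenotype.
    """

    chromosome: int
    block: int
    haplotypes: list[str]
    frequencies: dict[str, list[float]]
    penetrance: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("causal locus needs at least one haplotype")
        L = len(self.haplotypes[0])
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("haplotype strings must all have the same length")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype strings")
        for key, vec in self.frequencies.items():
            if len(vec) != len(self.haplotypes):
                raise ValueError(f"frequency vector for {key} has wrong length")
            if any(f < 0 for f in vec):
                raise ValueError(f"negative frequency for {key}")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"frequencies for {key} sum to {sum(vec)}, not 1")
        for hap, per_pop in self.penetrance.items():
            for pop, p in per_pop.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"penetrance[{hap}][{pop}]={p} outside [0,1]")

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0])

    def frequency_vector(self, subpop: str) -> np.ndarray:
        if subpop in self.frequencies:
            vec = self.frequencies[subpop]
        else:
            pop = subpop.split("_")[0]
            if pop not in self.frequencies:
                raise KeyError(f"no frequency vector for {subpop}")
            vec = self.frequencies[pop]
        return np.asarray(vec, dtype=float)


def pc1_like_causal_spec(chromosome: int = 0, block: int = 5) -> CausalLocusSpec:
    """Six-haplotype causal block shaped like the soybean pubescence-colour
    locus: one haplotype absent from WA and emerging in LR, incomplete
    penetrance everywhere outside WA."""
    haps = staircase_haplotypes(5, 6)
    freqs = {
        "WA": [0.006, 0.000, 0.588, 0.176, 0.159, 0.071],
        "LR": [0.424, 0.119, 0.207, 0.144, 0.091, 0.015],
        "RC": [0.379, 0.491, 0.011, 0.092, 0.020, 0.007],
    }
    pen_rows = [  # P(derived | hap, pop) per population WA/LR/RC
        (0.0, 0.363, 0.586),
        (0.0, 0.766, 0.968),
        (0.0, 0.195, 0.200),
        (0.0, 0.351, 0.122),
        (0.0, 0.361, 0.556),
        (0.0, 0.000, 0.667),
    ]
    penetrance = {
        h: dict(zip(POPULATIONS, row)) for h, row in zip(haps, pen_rows)
    }
    return CausalLocusSpec(chromosome, block, haps, freqs, penetrance)


def fc1_like_causal_spec(chromosome: int = 1, block: int = 5) -> CausalLocusSpec:
    """Five-haplotype causal block shaped like the soybean flower-colour
    locus: two haplotypes present in WA/LR but excluded from RC."""
    haps = staircase_haplotypes(4, 5)
    raw = {
        "WA": [0.066, 0.027, 0.346, 0.264, 0.297],
        "LR": [0.624, 0.318, 0.018, 0.033, 0.008],
        "RC": [0.482, 0.516, 0.002, 0.0, 0.0],
    }
    freqs = {k: (np.array(v) / np.sum(v)).tolist() for k, v in raw.items()}
    pen_rows = [
        (0.083, 0.077, 0.047),
        (1.000, 0.897, 0.883),
        (0.000, 0.143, 0.000),
        (0.083, 0.000, 0.000),
        (0.000, 0.000, 0.000),
    ]
    penetrance = {
        h: dict(zip(POPULATIONS, row)) for h, row in zip(haps, pen_rows)
    }
    return CausalLocusSpec(chromosome, block, haps, freqs, penetrance)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the germplasm study design."""

    n_accessions_per_subpop: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_SIZES)
    )
    n_chromosomes: int = 2
    n_blocks_per_chrom: int = 12
    snps_per_block: tuple[int, int] = (18, 24)  # inclusive range for neutral blocks
    causal_blocks: list[CausalLocusSpec] = field(
        default_factory=lambda: [pc1_like_causal_spec()]
    )
    missing_rate: float = 0.02
    het_rate: float = 0.01
    divergence_f: float = 0.05  # Balding-Nichols-style subpopulation divergence
    trait: str = "PC"
    categories: tuple[str, str] = ("brown", "gray")  # (ancestral, derived)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("missing_rate", self.missing_rate),
                           ("het_rate", self.het_rate)):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0,1), got {rate}")
        if not self.causal_blocks:
            raise ValueError("at least one causal block is required")
        sizes = self.n_accessions_per_subpop
        if any(n < 0 for n in sizes.values()):
            raise ValueError("subpopulation sizes must be >= 0")
        if sum(sizes.values()) < 2:
            raise ValueError("total population size must be >= 2")
        bad = set(sizes) - set(SUBPOPULATIONS)
        if bad:
            raise ValueError(f"unknown subpopulations: {sorted(bad)}")
        for spec in self.causal_blocks:
            if not 0 <= spec.chromosome < self.n_chromosomes:
                raise ValueError(f"causal chromosome {spec.chromosome} out of range")
            if not 0 <= spec.block < self.n_blocks_per_chrom:
                raise ValueError(f"causal block {spec.block} out of range")
        coords = {(s.chromosome, s.block) for s in self.causal_blocks}
        if len(coords) != len(self.causal_blocks):
            raise ValueError("duplicate causal block coordinates")

    @property
    def n_blocks(self) -> int:
        return self.n_chromosomes * self.n_blocks_per_chrom

    @property
    def n_neutral_blocks(self) -> int:
        return self.n_blocks - len(self.causal_blocks)

    @property
    def total_accessions(self) -> int:
        return sum(self.n_accessions_per_subpop.values())


@dataclass
class BlockTruth:
    """Ground truth for one simulated block."""

    block_id: str
    chrom: str
    snp_ids: list[str]
    haplotypes: list[str]  # catalogue of allele strings
    frequencies: dict[str, list[float]]  # per subpopulation
    causal: bool


@dataclass
class TruthRecord:
    """Everything the generator knows: block catalogues, pre-noise haplotype
    assignments (accession x block indices into each catalogue), and the
    penetrance model of the primary causal block."""

    accession_ids: list[str]
    blocks: list[BlockTruth]
    assignments: np.ndarray  # int, shape (n_accessions, n_blocks)
    primary_block_id: str
    penetrance: dict[str, dict[str, float]]

    def block_index(self, block_id: str) -> int:
        for i, b in enumerate(self.blocks):
            if b.block_id == block_id:
                return i
        raise KeyError(f"unknown block id: {block_id}")

    def haplotype_strings(self, block_id: str) -> list[str]:
        """Per-accession haplotype string at one block (pre-noise truth)."""
        i = self.block_index(block_id)
        cat = self.blocks[i].haplotypes
        return [cat[k] for k in self.assignments[:, i]]

    def genotype_codes(self) -> np.ndarray:
        """Rebuild the noise-free genotype code matrix from the assignments."""
        cols = []
        for i, b in enumerate(self.blocks):
            hapmat = np.array(
                [[int(c) for c in h] for h in b.haplotypes], dtype=np.int8
            )
            cols.append(hapmat[self.assignments[:, i]])
        return np.concatenate(cols, axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accession_ids": self.accession_ids,
            "blocks": [
                {
                    "block_id": b.block_id,
                    "chrom": b.chrom,
                    "snp_ids": b.snp_ids,
                    "haplotypes": b.haplotypes,
                    "frequencies": b.frequencies,
                    "causal": b.causal,
                }
                for b in self.blocks
            ],
            "assignments": self.assignments.tolist(),
            "primary_block_id": self.primary_block_id,
            "penetrance": self.penetrance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            accession_ids=d["accession_ids"],
            blocks=[BlockTruth(**b) for b in d["blocks"]],
            assignments=np.asarray(d["assignments"], dtype=int),
            primary_block_id=d["primary_block_id"],
            penetrance=d["penetrance"],
        )


def _neutral_pool(rng: np.random.Generator, n_snps: int, f: float):
    """Haplotype catalogue + per-subpopulation frequencies for a neutral block.

    Haplotypes are threshold-type ("generalized staircase"): each SNP gets a
    level in 1..k-1 and haplotype t carries the alternate allele exactly at
    SNPs with level <= t.  Any two SNPs then show at most three gametes, so
    D' = 1 inside the block while haplotypes still differ at many positions.
    A Dirichlet(3,..,3) base frequency vector is perturbed per subpopulation
    with a Balding-Nichols-style Dirichlet(base * (1-F)/F), giving mild
    structured divergence across subpopulations.
    """
    k = int(rng.integers(4, min(n_snps + 1, 8) + 1))
    levels = np.concatenate(
        [np.arange(1, k), rng.integers(1, k, size=n_snps - k + 1)]
    )
    levels = rng.permutation(levels)
    haps = [
        "".join("1" if lv <= t else "0" for lv in levels) for t in range(k)
    ]
    base = rng.dirichlet(3.0 * np.ones(k))
    base = np.clip(base, 1e-3, None)
    base /= base.sum()
    scale = (1.0 - f) / f
    freqs = {sp: rng.dirichlet(base * scale).tolist() for sp in SUBPOPULATIONS}
    return haps, freqs


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, AccessionMetadata, TruthRecord]:
    """Draw a structured inbred population with known causal blocks.

    One haplotype is drawn per accession per block from that accession's
    subpopulation frequency vector; the phenotype is Bernoulli in the
    penetrance of the primary causal haplotype; missing/heterozygous noise is
    injected afterwards.  Deterministic given ``config.seed``.
    """
    if config.total_accessions == 0:
        raise ValueError("zero-size population")
    rng = np.random.default_rng(config.seed)

    # Accessions, ordered by subpopulation.
    acc_rows = []
    for sp in SUBPOPULATIONS:
        n = config.n_accessions_per_subpop.get(sp, 0)
        pop, eco = sp.split("_")
        for _ in range(n):
            acc_rows.append((f"ACC{len(acc_rows):04d}", pop, eco))
    accession_ids = [r[0] for r in acc_rows]
    metadata = AccessionMetadata(
        pd.DataFrame(acc_rows, columns=["accession_id", "population", "ecoregion"])
    )
    subpop = (metadata.frame["population"] + "_" + metadata.frame["ecoregion"]).values
    n_acc = len(accession_ids)

    causal_at = {(s.chromosome, s.block): s for s in config.causal_blocks}

    # Blocks, genome order.
    blocks: list[BlockTruth] = []
    assignments = np.zeros((n_acc, config.n_blocks), dtype=int)
    snp_ids_all, chrom_all, pos_all = [], [], []
    code_cols = []
    for c in range(config.n_chromosomes):
        chrom_name = f"Gm{c + 1:02d}"
        for b in range(config.n_blocks_per_chrom):
            spec = causal_at.get((c, b))
            if spec is not None:
                n_snps = spec.n_snps
                haps = list(spec.haplotypes)
                freqs = {sp: spec.frequency_vector(sp).tolist()
                         for sp in SUBPOPULATIONS}
            else:
                lo, hi = config.snps_per_block
                n_snps = int(rng.integers(lo, hi + 1))
                haps, freqs = _neutral_pool(rng, n_snps, config.divergence_f)
            start = 1 + b * BLOCK_SPACING
            positions = [start + j * SNP_SPACING for j in range(n_snps)]
            snp_ids = [f"{chrom_name}_{p}" for p in positions]
            block_id = f"{chrom_name}_B{b:02d}"
            bi = len(blocks)
            # Draw one haplotype per accession from its subpopulation vector.
            assign = np.zeros(n_acc, dtype=int)
            for sp in SUBPOPULATIONS:
                mask = subpop == sp
                if not mask.any():
                    continue
                p = np.asarray(freqs[sp], dtype=float)
                assign[mask] = rng.choice(len(haps), size=mask.sum(), p=p)
            assignments[:, bi] = assign
            hapmat = np.array([[int(x) for x in h] for h in haps], dtype=np.int8)
            code_cols.append(hapmat[assign])
            snp_ids_all.extend(snp_ids)
            chrom_all.extend([chrom_name] * n_snps)
            pos_all.extend(positions)
            blocks.append(
                BlockTruth(block_id, chrom_name, snp_ids, haps, freqs,
                           causal=spec is not None)
            )

    codes_clean = np.concatenate(code_cols, axis=1)

    # Phenotype from the primary causal block.
    primary = config.causal_blocks[0]
    primary_id = f"Gm{primary.chromosome + 1:02d}_B{primary.block:02d}"
    pi = next(i for i, b in enumerate(blocks) if b.block_id == primary_id)
    pop_of_acc = metadata.frame["population"].values
    derived = np.zeros(n_acc, dtype=bool)
    for i in range(n_acc):
        hap = blocks[pi].haplotypes[assignments[i, pi]]
        if hap not in primary.penetrance:
            raise ValueError(
                f"penetrance map missing haplotype {hap!r} present at "
                f"nonzero frequency in the primary causal block"
            )
        p = primary.penetrance[hap].get(pop_of_acc[i], 0.0)
        derived[i] = rng.random() < p
    categories = np.where(derived, config.categories[1], config.categories[0])
    phenotype = PhenotypeTable(
        pd.DataFrame(
            {
                "accession_id": accession_ids,
                "trait": config.trait,
                "category": categories,
            }
        )
    )

    # Noise injection (missing wins over het at overlapping cells).
    codes = codes_clean.copy()
    u_missing = rng.random(codes.shape)
    u_het = rng.random(codes.shape)
    codes[u_het < config.het_rate] = 2
    codes[u_missing < config.missing_rate] = -1

    # Random but seeded REF/ALT nucleotides per SNP.
    bases = np.array(list("ACGT"))
    n_snps_total = codes.shape[1]
    ref_idx = rng.integers(0, 4, size=n_snps_total)
    alt_shift = rng.integers(1, 4, size=n_snps_total)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]

    genotypes = GenotypeMatrix(
        accession_ids=accession_ids,
        snp_ids=snp_ids_all,
        chrom=np.array(chrom_all, dtype=object),
        pos=np.array(pos_all, dtype=np.int64),
        codes=codes,
        ref=ref.astype(object),
        alt=alt.astype(object),
    )
    truth = TruthRecord(
        accession_ids=accession_ids,
        blocks=blocks,
        assignments=assignments,
        primary_block_id=primary_id,
        penetrance=primary.penetrance,
    )
    return genotypes, phenotype, metadata, truth


def write_dataset(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    metadata: AccessionMetadata,
    dir_path: str | Path,
    truth: TruthRecord | None = None,
) -> dict[str, Path]:
    """Write the simulated dataset (VCF + TSVs + optional truth JSON)."""
    geno_ids = set(genotypes.accession_ids)
    phen_ids = set(phenotypes.frame["accession_id"])
    meta_ids = set(metadata.frame["accession_id"])
    if not geno_ids == phen_ids == meta_ids:
        offending = sorted((geno_ids ^ phen_ids) | (geno_ids ^ meta_ids))
        raise ValueError(f"accession id mismatch across inputs: {offending}")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotype": out / "phenotypes.tsv",
        "metadata": out / "metadata.tsv",
    }
    write_vcf(genotypes, paths["vcf"])
    write_phenotype_tsv(phenotypes, paths["phenotype"])
    write_metadata_tsv(metadata, paths["metadata"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    return paths
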