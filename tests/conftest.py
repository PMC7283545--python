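import numpy as np
import pandas as pd
import pytest

import snpldb as s
from snpldb.io_formats import SUBPOPULATIONS


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset, shared across tests."""
    cfg = s.SimulationConfig(seed=42)
    return s.simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulated dataset (no missing, no het)."""
    cfg = s.SimulationConfig(missing_rate=0.0, het_rate=0.0, seed=42)
    return s.simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_markers(clean_sim):
    g, phen, meta, truth = clean_sim
    return s.assemble_markers(g)


def uniform_sizes(per_subpop: int) -> dict:
    return {sp: per_subpop for sp in SUBPOPULATIONS}


def two_hap_config(seed: int, n_per_subpop: int = 17, pen=(1.0, 0.0)):
    """One causal block with 2 haplotypes at 50/50 and given penetrances."""
    haps = s.staircase_haplotypes(4, 2)
    spec = s.CausalLocusSpec(
        chromosome=0,
        block=2,
        haplotypes=haps,
        frequencies={p: [0.5, 0.5] for p in ("WA", "LR", "RC")},
        penetrance={
            haps[0]: {p: pen[0] for p in ("WA", "LR", "RC")},
            haps[1]: {p: pen[1] for p in ("WA", "LR", "RC")},
        },
    )
    return s.SimulationConfig(
        n_accessions_per_subpop=uniform_sizes(n_per_subpop),
        n_chromosomes=1,
        n_blocks_per_chrom=6,
        causal_blocks=[spec],
        missing_rate=0.0,
        het_rate=0.0,
        seed=seed,
    )


def make_phenotype(accession_ids, labels, trait="T"):
    return s.PhenotypeTable(
        pd.DataFrame(
            {"accession_id": accession_ids, "trait": trait, "category": labels}
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
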