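import numpy as np
import pytest

from orchardkin import OrchardSimConfig, concat_samples, simulate_orchard
from orchardkin.genotypes import MISSING, GenotypeMatrix


def make_gm(dosage, roles=None, crops=None, **kwargs):
    """Small GenotypeMatrix with generated ids from a plain array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        roles=roles or ["seedling"] * n,
        crop_labels=crops or [""] * n,
        locus_ids=[f"l{j}" for j in range(L)],
        dosage=dosage,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise crop: 28 parents, 300 seedlings, 2000 loci."""
    cfg = OrchardSimConfig(
        n_parents=28,
        n_seedlings=300,
        n_loci=2000,
        selfing_rate=0.03,
        bpc_rate=0.30,
        genotype_error_rate=0.005,
        missing_rate=0.10,
        rng_seed=7,
    )
    return cfg, simulate_orchard(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free crop for exactness checks."""
    cfg = OrchardSimConfig(
        n_parents=28,
        n_seedlings=300,
        n_loci=2000,
        selfing_rate=0.03,
        bpc_rate=0.30,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        rng_seed=11,
    )
    return cfg, simulate_orchard(cfg)


def combined_matrix(sim):
    return concat_samples(sim.parents, sim.seedlings)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


MISSING_ = MISSING  # re-export for test modules
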