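import numpy as np
import pytest

from melonmap.simcross import (
    ChromosomeSpec,
    GenomeConfig,
    genotype_markers,
    simulate_genome,
    simulate_ril_population,
)


@pytest.fixture(scope="session")
def small_config():
    return GenomeConfig(
        chromosomes=(
            ChromosomeSpec("c1", 30_000_000, 80.0, n_scaffolds=8, n_markers=60),
            ChromosomeSpec("c2", 20_000_000, 60.0, n_scaffolds=6, n_markers=45),
        )
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config, seed=1)


@pytest.fixture(scope="session")
def small_pop(small_genome):
    return simulate_ril_population(small_genome, n=103, generations=8, seed=2)


@pytest.fixture(scope="session")
def clean_gm(small_pop):
    """Error-free, fully observed genotype matrix."""
    return genotype_markers(small_pop, error_rate=0.0, missing_rate=0.0, het_policy="set_missing", seed=3)


@pytest.fixture(scope="session")
def noisy_gm(small_pop):
    """Genotype matrix with realistic scoring error and missingness."""
    return genotype_markers(small_pop, error_rate=0.005, missing_rate=0.05, het_policy="set_missing", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120111)
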