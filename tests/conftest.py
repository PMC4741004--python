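import numpy as np
import pytest

from genophys import simulate


@pytest.fixture(scope="session")
def small_sim():
    """A compact genome set with all planted features, reused across tests."""
    params = simulate.GenomeSimParams(
        n_genomes=3,
        genome_len=60000,
        n_core_families=8,
        n_accessory_families=4,
        nucleotide_divergence=0.02,
        protein_divergence=0.02,
        island_specs=[(8000, 0.2)],
        rpsl_variants=["KK", "KR", "RK"],
        seed=101,
    )
    return simulate.simulate_genome_set(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
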