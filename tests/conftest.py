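import pytest

from paralogon import fixtures as fx
from paralogon.evo_sim import SimParams, simulate_history


@pytest.fixture(scope="session")
def sstr_genomes():
    return fx.sstr_genomes()


@pytest.fixture(scope="session")
def species_tree():
    return fx.vertebrate_species_tree()


@pytest.fixture(scope="session")
def windows():
    return fx.dating_windows()


@pytest.fixture(scope="session")
def noiseless_sim(species_tree):
    """Noiseless simulation: full retention, no rearrangements."""
    params = SimParams(
        n_families=12,
        n_ancestral_chromosomes=2,
        ohnolog_retention_prob=1.0,
        seed=3,
    )
    return simulate_history(species_tree, params)
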