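import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mitoedit import (
    SimConfig,
    call_sites,
    generate_genome,
    plant_edits,
    simulate_pileups,
)


@pytest.fixture(scope="session")
def default_sim():
    """One deterministic restorative strain shared across tests."""
    config = SimConfig(seed=11)
    genome, models = generate_genome(config)
    truth = plant_edits(genome, models, config)
    dna, rna = simulate_pileups(genome, truth, config)
    return config, genome, models, truth, dna, rna


@pytest.fixture(scope="session")
def default_sites(default_sim):
    config, genome, models, truth, dna, rna = default_sim
    return call_sites(dna, rna, genome, models)
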