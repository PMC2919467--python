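import pytest

from congenic.io import packaged_study_table, read_study_table
from congenic.simulate import (
    SimConfig,
    design_probes,
    simulate_experiment,
    simulate_genome,
)


@pytest.fixture(scope="session")
def studies():
    return read_study_table(packaged_study_table())


@pytest.fixture(scope="session")
def small_config():
    """Reduced genome for fast unit tests (one strain's worth of signal)."""
    return SimConfig(
        seed=42,
        n_chromosomes=3,
        chrom_length=10_000_000,
        genes_per_chrom=80,
        n_trans=5,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    genome = simulate_genome(small_config)
    probes = design_probes(genome.genes, genome.snps, small_config)
    exp, truth = simulate_experiment(genome, probes, small_config)
    return genome, probes, exp, truth
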