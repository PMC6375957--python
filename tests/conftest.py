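import pytest

from viralrp import PipelineConfig, SimulationConfig, generate_dataset


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic survey shared by read-only tests."""
    return generate_dataset(SimulationConfig(
        n_hosts=4, n_contigs=30, contig_len_nt=8000, host_genome_len=80_000,
        n_decoy_hosts=5, rng_seed=11,
    ))
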