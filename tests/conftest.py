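import pytest

from methylaxis.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        genome_size=40_000,
        n_chromosomes=2,
        n_genes=8,
        n_de_genes=4,
        gene_length_bp=2_000,
        n_dmrs=6,
        dmr_length_bp=800,
        spikein_length=3_000,
        n_replicates=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
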