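import pytest

from placenta_enhancers import SimulationConfig, simulate_dataset


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast study: 2 chromosomes, 120 genes, 30 enhancers, 9 samples."""
    defaults = dict(
        n_chromosomes=2,
        chrom_length_bp=1_000_000,
        n_genes=120,
        n_enhancers=30,
        n_samples_per_trimester=3,
        n_tfs_early=3,
        n_tfs_late=3,
        n_tfs_decoy=10,
        n_snps=2000,
        n_decoy_tres_per_sample=10,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the full study conditions (36 samples, 500 enhancers)."""
    return simulate_dataset(SimulationConfig(seed=5))
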