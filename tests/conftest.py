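import numpy as np
import pytest

from accessprior.simulate import (
    SimulationConfig,
    generate_accessibility_dataset,
    generate_expression_dataset,
    generate_ko_dataset,
)


def small_simulation_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down study for fast unit tests (same structure, fewer
    peaks/genes); acceptance tests use the full default configuration."""
    params = dict(
        seed=seed,
        n_chroms=2,
        chrom_length_bp=2_000_000,
        n_peaks_shared=60,
        n_peaks_tumor_specific=60,
        n_peaks_background=280,
        n_genes=200,
        n_nominated_genes=5,
        ko_target_set_size=10,
        ko_motif_target_count=4,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_config():
    return small_simulation_config()


@pytest.fixture(scope="session")
def dataset(small_config):
    return generate_accessibility_dataset(small_config)


@pytest.fixture(scope="session")
def expression(small_config, dataset):
    return generate_expression_dataset(small_config, dataset.truth)


@pytest.fixture(scope="session")
def ko_data(small_config, dataset):
    return generate_ko_dataset(small_config, dataset.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
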