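import numpy as np
import pytest
from hypothesis import settings

import scmultiome as sm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(**overrides) -> sm.SimConfig:
    """Desk-scale config shared by unit tests; overridable per test."""
    defaults = dict(
        n_cells=600,
        n_genes=200,
        n_peaks=300,
        n_tfs=6,
        n_celltypes=5,
        marker_genes_per_type=10,
        n_links_per_tf=8,
        seed=7,
    )
    defaults.update(overrides)
    return sm.SimConfig(**defaults)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def dataset_truth(config):
    return sm.simulate_multiome(config)


@pytest.fixture(scope="session")
def dataset(dataset_truth):
    return dataset_truth[0]


@pytest.fixture(scope="session")
def truth(dataset_truth):
    return dataset_truth[1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
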