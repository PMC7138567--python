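import warnings

import numpy as np
import pytest

from coexnet.network import adjacency, correlation_matrix
from coexnet.simulate import SyntheticConfig, generate_cohort_pair


@pytest.fixture(scope="session")
def small_pair():
    """Quick three-module cohort pair for unit tests."""
    cfg = SyntheticConfig(
        n_genes=200,
        n_samples_a=100,
        n_samples_b=100,
        module_sizes=(60, 30, 20),
        n_nonpreserved=1,
        seed=7,
    )
    return cfg, *generate_cohort_pair(cfg)


@pytest.fixture(scope="session")
def default_pair():
    """Cohort pair under the frozen default study conditions."""
    cfg = SyntheticConfig(seed=3)
    return cfg, *generate_cohort_pair(cfg)


@pytest.fixture(scope="session")
def default_networks(default_pair):
    """Power-6 adjacencies for both cohorts of the default pair."""
    cfg, ds_a, ds_b, truth = default_pair
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        am_a = adjacency(correlation_matrix(ds_a), 6)
        am_b = adjacency(correlation_matrix(ds_b), 6)
    return am_a, am_b


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
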