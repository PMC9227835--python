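import numpy as np
import pytest
from hypothesis import settings

from metabobench import CorrelationSpec, ScenarioConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def independent_spec():
    """M=40 mutually independent metabolites."""
    return CorrelationSpec(
        n_metabolites=40, n_clusters=4, within_cluster_rho=0.0,
        between_cluster_rho=0.0, target_mean_rho=0.0, jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def clustered_spec():
    """Small clustered spec with the default mean-0.40 structure."""
    return CorrelationSpec(n_metabolites=60, n_clusters=6)


@pytest.fixture(scope="session")
def small_dataset(clustered_spec):
    cfg = ScenarioConfig(n_subjects=150, correlation=clustered_spec, seed=7)
    return simulate_dataset(cfg)
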