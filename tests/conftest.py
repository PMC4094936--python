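import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prsgxe as P

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return P.SimulationConfig(n_discovery=300, n_target_pairs=120, n_snps=200,
                              n_causal=40, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(discovery_geno, discovery_cohort, target_geno, target_cohort)."""
    return P.simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)

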