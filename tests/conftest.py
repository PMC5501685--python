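import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coregrn as c

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_truth():
    """3-gene core truth used by several suites (deterministic)."""
    return c.generate_truth(3, 0, core_density=0.5, seed=11)


@pytest.fixture(scope="session")
def tiny_data(tiny_truth):
    return c.generate_data(tiny_truth, times=(0, 1, 2, 4, 8, 12), seed=12)


@pytest.fixture(scope="session")
def decay_structure():
    """Single gene, no edges: analytic test bed."""
    return c.NetworkStructure(core_genes=("A",))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
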