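import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cexqtl.fixtures import make_fixture_genome

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """Small worm-like fixture genome: 6 chromosomes (one X), arm-biased map."""
    return make_fixture_genome(n_markers=240, seed=7)


@pytest.fixture(scope="session")
def gmap(genome):
    return genome[0]


@pytest.fixture(scope="session")
def markers(genome):
    return genome[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
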