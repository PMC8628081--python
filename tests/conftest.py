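import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tecoevo.genome import Genome

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def minimal_genome():
    """One copy of each of the 10 essential genes, nothing else."""
    return Genome.initial(10, 0)


@pytest.fixture
def founder_genome():
    """The evolutionary founder: 10 essential genes + 30 non-coding."""
    return Genome.initial(10, 30)


def random_genome(rng, length=40, p_te=0.2, p_nc=0.3):
    """A random genome with the given class mix (may be non-viable)."""
    kinds = rng.choice(3, size=length, p=[1 - p_te - p_nc, p_te, p_nc])
    codes = np.where(kinds == 0, rng.integers(1, 11, size=length),
                     np.where(kinds == 1, 127, 0)).astype(np.int8)
    phis = np.where(codes == 127, rng.random(length), 0.0).astype(np.float32)
    return Genome(codes, phis)
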