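import numpy as np
import pytest

from asaq.simulate import gm_quartet


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def exact_quartet(rng):
    """Exact pattern distribution from a random stochastic GM quartet on 12|34."""
    lens = rng.uniform(0.05, 0.8, 5)
    inst = gm_quartet(lens[:4], lens[4], rng)
    return inst


def random_distribution(rng):
    """A random (Dirichlet) quartet pattern distribution."""
    from asaq.patterns import SitePatternDistribution

    v = rng.dirichlet(np.ones(256))
    v = v / v.sum()
    return SitePatternDistribution(taxa=("1", "2", "3", "4"), values=v, n_sites=1000)
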