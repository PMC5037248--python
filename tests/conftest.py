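import numpy as np
import pytest

from attribfrac.simulate import demo_scenario, generate_population, independence_scenario


@pytest.fixture(scope="session")
def demo_sample():
    """Small positively-correlated five-factor sample shared across tests."""
    return generate_population(demo_scenario(n_individuals=20_000, seed=7))


@pytest.fixture(scope="session")
def independent_sample():
    """Same marginals and risk ratios, identity latent correlation."""
    return generate_population(independence_scenario(n_individuals=100_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20130)
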