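import numpy as np
import pytest

from snpcount import SimulationSpec, fit_nb, gen_dataset, hermite_rule


@pytest.fixture(scope="session")
def rule30():
    return hermite_rule(30)


@pytest.fixture(scope="session")
def rule60():
    return hermite_rule(60)


@pytest.fixture(scope="session")
def loggamma_data():
    """One draw of the log-gamma benchmark design (alpha^2 = 0.8, n = 1000)."""
    data, eps = gen_dataset(SimulationSpec.loggamma(alpha2=0.8, n=1000, seed=0))
    return data, eps


@pytest.fixture(scope="session")
def loggamma_nb_fit(loggamma_data):
    data, _ = loggamma_data
    return fit_nb(data)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
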