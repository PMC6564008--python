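import datetime as dt

import numpy as np
import pytest

import hpmatrix as hx


@pytest.fixture(scope="session")
def params():
    return hx.load_parameters("default")


@pytest.fixture(scope="session")
def host_params(params):
    return params.host


@pytest.fixture(scope="session")
def para_params(params):
    return params.parasitoid


@pytest.fixture(scope="session")
def const25():
    """Constant 25 degC series (the laboratory reference temperature)."""
    return hx.TemperatureSeries(dt.date(2017, 6, 22), np.full(90, 25.0))


@pytest.fixture(scope="session")
def climatology():
    """One realization of the synthetic growing-season climatology."""
    return hx.synthetic_climatology(dt.date(2017, 6, 22), 90, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230622)


def random_state(rng, scale=50.0):
    """A random valid population state with N comfortably below K."""
    n = rng.uniform(0.0, scale, size=5)
    p = rng.uniform(0.0, scale / 5.0, size=3)
    return hx.PopulationState(n, p)
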