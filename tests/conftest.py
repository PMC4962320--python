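import numpy as np
import pytest

from udsbm import ModelParams


@pytest.fixture(scope="session")
def brownian_params():
    """Constant-coefficient (alpha = 1) reference process."""
    return ModelParams(T0=1.0, gamma0=1.0, m=1.0, tau0=1e6, alpha=1.0)


@pytest.fixture(scope="session")
def ultraslow_params():
    """The gamma0 = 1, tau0 = 30, T0 = D0 = m = 1 ultraslow set."""
    return ModelParams(T0=1.0, gamma0=1.0, m=1.0, tau0=30.0, alpha=0.0)


@pytest.fixture(scope="session")
def subdiffusive_params():
    """alpha = 1/2 with wide scale separation (tau0 = 1e5)."""
    return ModelParams(T0=1.0, gamma0=1.0, m=1.0, tau0=1e5, alpha=0.5)


def loglog_slope(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])
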