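import numpy as np
import pytest

from slisemap import Slisemap
from slisemap.datasets import generate_piecewise_1d


@pytest.fixture(scope="session")
def two_regime_data():
    """Absolute-value-shaped two-regime regression data (shared fixture)."""
    return generate_piecewise_1d(
        n=150, slopes=(-1.0, 1.0), breakpoints=(0.0,), noise_sd=0.1, seed=7
    )


@pytest.fixture(scope="session")
def two_regime_fit(two_regime_data):
    """A fitted supervised embedding on the two-regime data."""
    sm = Slisemap(random_state=7)
    sm.fit(two_regime_data.X, two_regime_data.y)
    return sm


@pytest.fixture(scope="session")
def small_fit():
    """Tiny fitted model for cheap round-trip / metric tests."""
    data = generate_piecewise_1d(n=40, slopes=(-1.0, 1.0), breakpoints=(0.0,),
                                 noise_sd=0.1, seed=3)
    sm = Slisemap(random_state=3, max_iter=100, max_rounds=10)
    sm.fit(data.X, data.y)
    return sm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
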