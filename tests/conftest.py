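import numpy as np
import pytest

import avapoiss as ap


@pytest.fixture(scope="session")
def hpp_series():
    """HPP at rate 1, 10^6 bins: the workhorse reference process."""
    return ap.simulate_hpp(1.0, 10**6, seed=12345)


@pytest.fixture(scope="session")
def hpp_catalog(hpp_series):
    return ap.extract_avalanches(hpp_series)


@pytest.fixture(scope="session")
def four_rate_envelope():
    """Equiprobable rates proportional to {1,2,5,10}, renormalized to mean 1."""
    return ap.RateEnvelope.piecewise([1, 2, 5, 10], 250_000, mean_rate=1.0)


@pytest.fixture(scope="session")
def four_rate_series(four_rate_envelope):
    return ap.simulate_ipp(four_rate_envelope, 10**6, seed=777)


@pytest.fixture(scope="session")
def four_rate_mixture_nodes():
    rates = np.array([1.0, 2.0, 5.0, 10.0]) / 4.5
    return rates, np.full(4, 0.25)


@pytest.fixture
def toy_series():
    """The hand-computable six-bin example [0,2,1,0,3,0]."""
    return ap.BinnedSeries([0, 2, 1, 0, 3, 0])
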