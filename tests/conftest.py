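import numpy as np
import pytest

import cyclefit as cf

#: reference period of the oscillatory Goodwin fixture at nominal rates,
#: frozen from the shooting solve (verified against peak timing in tests)
GOODWIN_PERIOD = 19.80870977139


@pytest.fixture(scope="session")
def goodwin():
    return cf.goodwin_fixture()


@pytest.fixture(scope="session")
def damped():
    return cf.damped_fixture()


@pytest.fixture(scope="session")
def goodwin_cycle(goodwin):
    return cf.find_limit_cycle(
        goodwin, goodwin.nominal_params, np.ones(3), goodwin.period_hint
    )


@pytest.fixture(scope="session")
def truth30(goodwin, goodwin_cycle):
    """Noise-free truth sampled at M=30 equispaced points over one period."""
    return cf.sample_true_data(
        goodwin, goodwin.nominal_params, 30, cycle=goodwin_cycle
    )


@pytest.fixture(scope="session")
def quiet_dataset(truth30):
    """Noise-free means carrying realistic sigma weights (xi=5%)."""
    sigma = cf.NoiseModel(xi=0.05, eta=0.001).sigma(truth30.means)
    return cf.TimeSeriesDataset(
        truth30.times, truth30.means, sigma, truth30.state_names
    )
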