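import numpy as np
import pytest

from viscofit import MaterialParameters
from viscofit.experiment import ProtocolConfig, make_protocol


@pytest.fixture
def params():
    """Mid-box brain-tissue-like parameter set."""
    return MaterialParameters(mu_inf=500.0, alpha_inf=-10.0, mu_1=800.0, alpha_1=-12.0, eta_1=3000.0)


@pytest.fixture
def short_protocol_config():
    """A 51-sample protocol with all four segment types, for fast simulations."""
    return ProtocolConfig(
        dt=0.1,
        ct_cycles=1,
        ct_amplitude=0.08,
        ct_period=2.0,
        hold_amplitude=0.08,
        ramp_time=0.3,
        hold_time=0.4,
        shear_cycles=1,
        shear_amplitude=0.08,
        shear_period=1.0,
    )


@pytest.fixture
def short_protocol(short_protocol_config):
    return make_protocol(short_protocol_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
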