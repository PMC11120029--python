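import numpy as np
import pytest

from clampkin.schemes import one_step_binding_scheme, two_step_binding_scheme
from clampkin.synth import InstrumentModel, ResponseModel, protocol_design, simulate_trace_set


@pytest.fixture
def two_step_scheme():
    """Reference two-step binding scheme with simple round-number rates."""
    return two_step_binding_scheme(5e6, 50.0, 15.0, 10.0)


@pytest.fixture
def clamp_response():
    """Bright substrate, dimmer enzyme-bound species."""
    return ResponseModel(0.05, {"S": 1.0e6, "ES": 0.7e6, "ES*": 0.6e6})


@pytest.fixture
def small_noiseless_traceset(clamp_response):
    """Fast noiseless two-step trace set on the enzyme-varied design."""
    scheme = two_step_binding_scheme(2e7, 100.0, 5.0, 20.0)
    instrument = InstrumentModel(noise_sd=0.0, seed=0, n_samples=120)
    return simulate_trace_set(scheme, clamp_response, instrument, protocol_design())
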