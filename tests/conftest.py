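import numpy as np
import pytest

import ringosc as ro


@pytest.fixture(scope="session")
def repressilator():
    return ro.builtin_network("repressilator")


@pytest.fixture(scope="session")
def mu40():
    return ro.dilution_rate_from_time(40.0)


@pytest.fixture(scope="session")
def osc_trajectory(repressilator):
    """A sustained 3-node oscillation at t_d = 40 min, reused across tests."""
    reactor = ro.ReactorSettings.from_dilution_time(40.0)
    return ro.simulate(repressilator, reactor, ro.RingState.pulse(3))


@pytest.fixture(scope="session")
def hill_truth():
    return {"ymin": 0.05, "K_M": 5.0, "n": 2.0, "v_max": 1.0}
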