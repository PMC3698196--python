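import pytest

from qus.pipeline import default_roi_plan
from qus.synthetic_rf import CohortConfig, TissueResponse, make_pulse, simulate_reference_echo


@pytest.fixture(scope="session")
def pulse():
    """Default transmit pulse: 6 MHz, 50% fractional bandwidth, 35 MHz sampling."""
    return make_pulse(6.0, 0.5, 35.0, 2.0)


@pytest.fixture(scope="session")
def reference(pulse):
    """Quartz-flat calibration echo at the 15 mm focus."""
    return simulate_reference_echo(pulse, 15.0)


@pytest.fixture(scope="session")
def roi_plan():
    """The standard three-ROI plan of the default acquisition geometry."""
    return default_roi_plan(CohortConfig())


@pytest.fixture(scope="session")
def control_response():
    return TissueResponse(true_slope=-10.66, true_midband=-57.10)


@pytest.fixture(scope="session")
def treated_response():
    return TissueResponse(true_slope=-5.49, true_midband=-49.81)
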