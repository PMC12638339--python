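import numpy as np
import pytest
from hypothesis import settings

from wexsim.bloch import WATER_BLOOD_1p5T
from wexsim.calibration import calibrate_amplitude, default_delta_f_grid
from wexsim.pulses import table_pulse_params

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water():
    return WATER_BLOOD_1p5T


@pytest.fixture(scope="session")
def delta_f_grid():
    return default_delta_f_grid()


@pytest.fixture(scope="session")
def calibrations():
    """Table-default calibrations for the three water-excitation pulses."""
    return {name: calibrate_amplitude(table_pulse_params(name)) for name in ("borr", "libre", "libor")}
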