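import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gelphylo.weight_calibration import CalibrationModel

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def model():
    """A realistic migration model: 5000 bp at the wells, ~half a decade
    of log-size per 230 rows."""
    return CalibrationModel(alpha=-0.01, beta=math.log(5000.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
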