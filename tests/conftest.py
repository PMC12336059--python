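import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


@pytest.fixture
def bold_protocol_default():
    from cvrquant.protocol import bold_protocol

    return bold_protocol()


@pytest.fixture
def pc_protocol_default():
    from cvrquant.protocol import pc_protocol

    return pc_protocol()


@pytest.fixture
def calib():
    from cvrquant.trustox import CalibrationModel

    return CalibrationModel()
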