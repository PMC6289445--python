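import numpy as np
import pytest

from fnirsvmd import SessionDesign, build_expected_response


@pytest.fixture
def design():
    """Reference session design: 60 s baseline + 10 × (15 s + 30 s), 1.81 Hz."""
    return SessionDesign()


@pytest.fixture
def xr(design):
    """Expected response regressor for the default 35 s epoch window."""
    return build_expected_response(design.stimulus_s, design.sampling_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
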