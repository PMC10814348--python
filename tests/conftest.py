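import numpy as np
import pytest

from hp13c.containers import AcquisitionParams, BolusParams, KineticParams


@pytest.fixture
def acq():
    """Default dynamic schedule: 20 x 3 s, flips (20, 30, 30), 2 s delay."""
    return AcquisitionParams()


@pytest.fixture
def nawm_rates():
    """Rates at the scale reported for normal-appearing white matter."""
    return KineticParams(k_pl=0.015, k_pb=0.003)


@pytest.fixture
def bolus():
    return BolusParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
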