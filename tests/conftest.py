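import numpy as np
import pytest

from stairmwi import (
    PD_PROTOCOL,
    STAIR_PROTOCOL,
    PhantomSpec,
    QuantConstants,
    calibrate_peak_b1,
    make_hs_pulse,
)


@pytest.fixture(scope="session")
def constants():
    return QuantConstants()


@pytest.fixture(scope="session")
def stair_seq():
    return STAIR_PROTOCOL


@pytest.fixture(scope="session")
def pd_seq():
    return PD_PROTOCOL


@pytest.fixture(scope="session")
def calibrated_b1():
    """Peak B1 (Hz) calibrated once for the whole suite."""
    return calibrate_peak_b1()


@pytest.fixture(scope="session")
def calibrated_pulse(calibrated_b1):
    return make_hs_pulse(peak_b1_hz=calibrated_b1)


@pytest.fixture(scope="session")
def small_spec():
    """A small noiseless phantom spec for fast geometric tests."""
    return PhantomSpec(shape=(32, 32, 9), noise_sigma=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
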