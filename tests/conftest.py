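import numpy as np
import pytest

from fmpools.synthetic import CalibratedDefaults, Fig2Timeline, calibrate


@pytest.fixture(scope="session")
def defaults() -> CalibratedDefaults:
    """Run-time calibration of the synthetic biexponential defaults."""
    return calibrate()


@pytest.fixture(scope="session")
def timeline() -> Fig2Timeline:
    return Fig2Timeline()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
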