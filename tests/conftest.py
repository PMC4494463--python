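import pytest

import dualhorizon as dh


@pytest.fixture(scope="session")
def calib():
    """Default lambda=0 calibration (300 arcmin, 360 detectors), built once."""
    return dh.get_calibration()


@pytest.fixture(scope="session")
def default_params():
    return dh.ObserverParams()
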