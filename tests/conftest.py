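import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plasmorec.config import SensorConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SensorConfig:
    return SensorConfig()


@pytest.fixture(scope="session")
def gold_nk_table():
    """(wavelength_m, n, k) columns of the tabulated gold reference data."""
    path = __file__.rsplit("/", 1)[0] + "/data/gold_nk.txt"
    data = np.loadtxt(path)
    return data[:, 0] * 1e-9, data[:, 1], data[:, 2]
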