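import pytest

from thyrocea import default_config, make_toy_config
from thyrocea.calibration import calibrated_config


@pytest.fixture(scope="session")
def base_cfg():
    return default_config()


@pytest.fixture(scope="session")
def calibrated(base_cfg):
    """Calibrated base-case configuration plus the calibration results."""
    cfg, results = calibrated_config(base_cfg)
    return cfg, results


@pytest.fixture(scope="session")
def cal_cfg(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def toy_two_state():
    return make_toy_config("two_state", death_prob=0.1, discount_rate=0.045)


@pytest.fixture(scope="session")
def toy_three_state():
    return make_toy_config("three_state", death_prob=0.05, discount_rate=0.045,
                           relapse_prob=0.2, relapse_cost=100.0, relapse_utility=0.8)
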