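import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hoppertrace import fixtures
from hoppertrace.metfield import MetField
from hoppertrace.synthetic import WindScenario, gen_windfield

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def east_wind_field() -> MetField:
    """Uniform 10 m/s eastward wind, 20 degC, covering southern China."""
    return gen_windfield(
        WindScenario(
            kind="uniform", speed=10.0, bearing_deg=90.0, temp_C=20.0,
            lat_range=(15.0, 35.0), lon_range=(95.0, 120.0),
        )
    )


@pytest.fixture(scope="session")
def calm_field() -> MetField:
    return gen_windfield(WindScenario(kind="uniform", speed=0.0, temp_C=20.0))


@pytest.fixture(scope="session")
def cold_field() -> MetField:
    """Uniform 10 degC: below the 16.5 degC flight floor everywhere."""
    return gen_windfield(WindScenario(kind="uniform", speed=10.0, temp_C=10.0))


@pytest.fixture(scope="session")
def tox_tables() -> pd.DataFrame:
    return fixtures.load_toxicity_tables()


# the published susceptibility groups of the 15 destination sites
GROUP_A = {"Hongjiang", "Linli", "Longshan", "Hanshou", "Zhijiang"}
GROUP_B = {"Dongan", "Shuangfeng", "Ningxiang", "Linxiang", "Xiangyin", "Qidong"}
GROUP_C = {"Daoxian", "Youxian", "Guiyang", "Yizhang"}
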