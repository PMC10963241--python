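import numpy as np
import pytest
from hypothesis import settings

from crowdkin import REFERENCE_PARAMETER_SETS, SCParameters

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt_params() -> SCParameters:
    """Wild-type ambient-temperature reference parameter set."""
    return REFERENCE_PARAMETER_SETS["30C"]["WT"]


@pytest.fixture(scope="session")
def table1_sets() -> dict[str, SCParameters]:
    """All four ambient-temperature (30C) reference parameter sets."""
    return REFERENCE_PARAMETER_SETS["30C"]


@pytest.fixture(scope="session")
def ts55_params() -> SCParameters:
    """Thermostable-variant elevated-temperature (55C) reference set."""
    return REFERENCE_PARAMETER_SETS["55C"]["TS"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
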