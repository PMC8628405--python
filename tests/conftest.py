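import pytest
from hypothesis import HealthCheck, settings

from opsinsites.align import SubstitutionMatrix
from opsinsites.sites import load_scheme

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def opsin_scheme():
    return load_scheme("bovine_rhodopsin")


@pytest.fixture(scope="session")
def rlbp1_scheme():
    return load_scheme("human_RLBP1")
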