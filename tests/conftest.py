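import pytest
from hypothesis import HealthCheck, settings

from bfcost import default_ontario_2019, run_all

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return default_ontario_2019()


@pytest.fixture(scope="session")
def default_run(params):
    return run_all(params)
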