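import pytest
from hypothesis import HealthCheck, settings

from hybridiag import default_catfish_panel, make_table2_fixture

settings.register_profile(
    "fixed", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def panel():
    return default_catfish_panel()


@pytest.fixture(scope="session")
def table2():
    """The deterministic 84-sample survey fixture."""
    return make_table2_fixture()
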