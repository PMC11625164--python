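import pytest
from hypothesis import settings

from hmrisk import load_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """The shipped reproduction profile (Dhaleshwari River survey)."""
    return load_config("dhaleshwari")


@pytest.fixture(scope="session")
def adult(config):
    return config.scenarios["adult"]


@pytest.fixture(scope="session")
def child(config):
    return config.scenarios["child"]
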