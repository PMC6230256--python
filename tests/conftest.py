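import pytest
from hypothesis import settings

from riskstrat.params import default_parameters, toy_parameters

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def toy_params():
    return toy_parameters()


@pytest.fixture(scope="session")
def default_sweep(default_params):
    """Full 101-strategy sweep on the packaged defaults (shared, ~0.2 s)."""
    from riskstrat.strategies import sweep

    return sweep(default_params)
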