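import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phoscea import default_parameters
from phoscea.economics import evaluate


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_result(base_params):
    """Deterministic base-case evaluation, shared across tests."""
    return evaluate(base_params)
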