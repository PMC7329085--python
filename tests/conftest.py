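import pytest

from lynchcea import default_parameters, run_pipeline


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_result(params):
    """Base-case pipeline run shared across tests (read-only)."""
    return run_pipeline(params)
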