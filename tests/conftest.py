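import pytest

from tnbc_cea.config import load_config


@pytest.fixture(scope="session")
def base_spec():
    """Shipped base case: loglogistic curves + published economic inputs."""
    return load_config(None)


@pytest.fixture(scope="session")
def base_traces(base_spec):
    return base_spec.traces()


@pytest.fixture(scope="session")
def base_result(base_spec):
    return base_spec.base_case()
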