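import pytest
from hypothesis import settings

from ins_incidence.fixtures import netherlands_registry, paris_registry

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def nl():
    return netherlands_registry()


@pytest.fixture(scope="session")
def paris():
    return paris_registry()
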