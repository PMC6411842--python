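import pytest
from hypothesis import settings

from rloopmut.synthetic_supplement import synthetic_catalog, synthetic_reference

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    return synthetic_reference()


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()
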