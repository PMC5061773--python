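import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from tubuliq.catalog import packaged_catalog
from tubuliq.mass_core import reporters_from_catalog


@pytest.fixture(scope="session")
def pd_catalog():
    return packaged_catalog("Pd")


@pytest.fixture(scope="session")
def pta_catalog():
    return packaged_catalog("Pta")


@pytest.fixture(scope="session")
def pd_reporters(pd_catalog):
    return reporters_from_catalog(pd_catalog)
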