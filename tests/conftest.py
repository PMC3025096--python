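import pytest

from lensphos import catalog as cat


@pytest.fixture(scope="session")
def site_catalog():
    """The packaged full normal-lens phosphosite catalog (73 observations)."""
    return cat.load_packaged_catalog("sites")


@pytest.fixture(scope="session")
def differential_catalog():
    """The packaged normal-vs-cataract differential catalog (30 observations)."""
    return cat.load_packaged_catalog("differential")


@pytest.fixture(scope="session")
def known_sites():
    return cat.load_known_sites()
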