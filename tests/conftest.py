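import pytest

from sacph.reference import human_sac_reference, human_site_map


@pytest.fixture(scope="session")
def reference():
    return human_sac_reference()


@pytest.fixture(scope="session")
def sites():
    return human_site_map()
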