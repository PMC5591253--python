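import pytest

from ecositemap import load_default_grid


@pytest.fixture(scope="session")
def acadian_grid():
    return load_default_grid("acadian")


@pytest.fixture(scope="session")
def mb_grid():
    return load_default_grid("maritime_boreal")
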