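import pytest

from psimelt import default_parameters, fixture_index, table_fixtures


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def fixtures():
    return table_fixtures()


@pytest.fixture(scope="session")
def fix_idx():
    return fixture_index()
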