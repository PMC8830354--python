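import pytest

from miadm import build_fixture_table, load_base_parameters


@pytest.fixture(scope="session")
def base_params():
    return load_base_parameters()


@pytest.fixture(scope="session")
def fixture_table():
    return build_fixture_table()
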