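import pytest

from cystindex import load_fixture, reproduce, screen_all


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_decisions(fixture_table):
    return screen_all(fixture_table)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_table):
    return reproduce(table=fixture_table)
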