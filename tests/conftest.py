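import pytest

from copdlc import default_panel, table_fixture


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def fixture_cohort(panel):
    return table_fixture(panel)
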