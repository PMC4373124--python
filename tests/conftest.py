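import pytest

from haplotrace.simulate import (
    fixture_frequency_tables,
    fixtures_from_tables,
    make_fixture_panel,
    synthetic_hvs1_reference,
)


@pytest.fixture(scope="session")
def panel():
    """(y_tree, markers, mt_table) miniature fixture panel."""
    return make_fixture_panel()


@pytest.fixture(scope="session")
def y_tree(panel):
    return panel[0]


@pytest.fixture(scope="session")
def markers(panel):
    return panel[1]


@pytest.fixture(scope="session")
def mt_table(panel):
    return panel[2]


@pytest.fixture(scope="session")
def reference():
    return synthetic_hvs1_reference()


@pytest.fixture(scope="session")
def fixtures():
    """Reconstructed PopulationSpecs for the three study populations."""
    return fixtures_from_tables()


@pytest.fixture(scope="session")
def fixture_tables():
    """(Y, mtDNA) FrequencyTables reconstructed from the printed tables."""
    return fixture_frequency_tables()
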