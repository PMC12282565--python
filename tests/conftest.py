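import pytest

from fasila.cohort import expand_fixture, table1_fixture
from fasila.io import records_to_dataframe
from fasila.report import score_dataframe


@pytest.fixture(scope="session")
def table1_spec():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_records(table1_spec):
    return expand_fixture(table1_spec)


@pytest.fixture(scope="session")
def table1_df(table1_records):
    return records_to_dataframe(table1_records)


@pytest.fixture(scope="session")
def table1_scored(table1_df):
    scored, n_flagged = score_dataframe(table1_df)
    assert n_flagged == 0
    return scored
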