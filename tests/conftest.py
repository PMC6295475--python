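import pytest

from syntherm import GibbsTable
from syntherm.synthetic_data import reference_scenarios


@pytest.fixture(scope="session")
def table():
    return GibbsTable.default()


@pytest.fixture()
def scenarios():
    return reference_scenarios()


@pytest.fixture()
def msao(scenarios):
    return scenarios["M-SAO"]


@pytest.fixture()
def ssao(scenarios):
    return scenarios["S-SAO"]
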