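import pytest

from costkit import (phase_summary, table2_fixture, unit_delivery_cost)


@pytest.fixture(scope="session")
def fixture_ledger():
    return table2_fixture()


@pytest.fixture(scope="session")
def delivery_breakdown(fixture_ledger):
    return unit_delivery_cost(fixture_ledger)


@pytest.fixture(scope="session")
def training_unit_cost(fixture_ledger):
    return phase_summary(fixture_ledger, "training").unit_cost
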