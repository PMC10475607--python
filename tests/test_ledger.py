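"""Ledger data model, validation and CSV/JSON round trips."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costkit import (CostItem, CostLedger, FormatError, read_ledger,
                     table2_fixture, validate_ledger, write_ledger)
from costkit.errors import LedgerValidationError


def item(item_id="x", phase="development", cls="recurrent", price="10",
         **kw):
    return CostItem(item_id=item_id, label=f"label {item_id}", phase=phase,
                    cost_class=cls, cost_behavior="variable",
                    unit_price=Decimal(price), **kw)


class TestFixture:
    def test_phase_item_counts(self, fixture_ledger):
        assert len(fixture_ledger.by_phase("development")) == 4
        assert len(fixture_ledger.by_phase("pretest")) == 1
        assert len(fixture_ledger.by_phase("training")) == 1
        assert len(fixture_ledger.by_phase("delivery")) == 5

    def test_global_parameters(self, fixture_ledger):
        assert fixture_ledger.cohort_size == 100
        assert fixture_ledger.discount_rate == 0.03
        assert fixture_ledger.exchange_rate == 74.0

    def test_validates_cleanly(self, fixture_ledger):
        report = validate_ledger(fixture_ledger)
        assert report.ok and not report.issues

    def test_phase_sums_match_published_totals(self, fixture_ledger):
        """Component sums agree with the printed phase totals within the
        table's own rounding slack (printed development total 6,59,447 vs
        component sum 6,59,444)."""
        dev = sum(i.ledger_cost() for i in fixture_ledger.by_phase("development"))
        pre = sum(i.ledger_cost() for i in fixture_ledger.by_phase("pretest"))
        assert abs((dev + pre) - 659447) <= 3
        assert pre == 11620
        assert sum(i.ledger_cost()
                   for i in fixture_ledger.by_phase("training")) == 134002

    def test_delivery_components(self, fixture_ledger):
        costs = {i.item_id: i.ledger_cost()
                 for i in fixture_ledger.by_phase("delivery")}
        assert costs["delivery_sms_calls"] == 160
        assert costs["delivery_phone_bill"] == Decimal("0.15")
        assert sum(costs.values()) == Decimal("272.15")


class TestValidation:
    @pytest.mark.parametrize("bad_item, fragment", [
        (item(cls="capital"), "useful_life_years required"),
        (item(apportionment_fraction=Decimal("1.3")), "apportionment_fraction"),
        (item(apportionment_fraction=Decimal("0")), "apportionment_fraction"),
        (item(price="-5"), "unit_price"),
        (item(quantity=0), "quantity"),
        (item(useful_life_years=3), "only valid on capital"),
        (item(cls="capital", useful_life_years=0.5), "useful_life_years"),
        (item(minutes_per_patient=5.0), "minutes_per_patient"),
        (item(phase="banana"), "phase"),
    ])
    def test_item_invariants_reported(self, bad_item, fragment):
        report = validate_ledger(CostLedger(items=[bad_item]))
        assert not report.ok
        assert any(fragment in i.message for i in report.errors())

    def test_duplicate_ids(self):
        report = validate_ledger(CostLedger(items=[item("a"), item("a")]))
        assert any("duplicate" in i.message for i in report.errors())

    def test_per_patient_capital_needs_no_life(self):
        # an already-annualized per-patient capital line is legal
        led = CostLedger(items=[item("c", phase="delivery", cls="capital",
                                     per_patient=True)])
        assert validate_ledger(led).ok

    def test_bad_global_parameters(self):
        report = validate_ledger(CostLedger(discount_rate=0.5, cohort_size=0))
        messages = " ".join(i.message for i in report.errors())
        assert "discount_rate" in messages and "cohort_size" in messages


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_fixture_round_trip(self, fixture_ledger, tmp_path, fmt):
        path = tmp_path / f"ledger.{fmt}"
        write_ledger(fixture_ledger, path, fmt)
        assert read_ledger(path, fmt) == fixture_ledger

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_empty_ledger_round_trip(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        write_ledger(CostLedger(), path, fmt)
        back = read_ledger(path, fmt)
        assert back.items == [] and back == CostLedger()

    def test_money_serialized_two_dp(self, tmp_path):
        led = CostLedger(items=[item("h", apportionment_fraction=Decimal("0.5"))])
        path = tmp_path / "l.csv"
        write_ledger(led, path, "csv")
        body = path.read_text()
        assert "10.00" in body and "0.50" in body

    def test_indian_digit_grouping_accepted(self, tmp_path):
        path = tmp_path / "l.csv"
        write_ledger(CostLedger(items=[item("w")]), path, "csv")
        patched = path.read_text().replace("10.00", '"4,91,040"')
        path.write_text(patched)
        assert read_ledger(path).items[0].unit_price == 491040

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text("item_id,label\na,b\n")
        with pytest.raises(FormatError, match="unit_price"):
            read_ledger(path)

    def test_duplicate_id_rejected_on_read(self, tmp_path):
        path = tmp_path / "l.csv"
        write_ledger(CostLedger(items=[item("a"), item("b")]), path, "csv")
        path.write_text(path.read_text().replace("b,label b", "a,label b"))
        with pytest.raises(LedgerValidationError, match="duplicate"):
            read_ledger(path)

    def test_write_refuses_invalid_ledger(self, tmp_path):
        led = CostLedger(items=[item(cls="capital")])
        with pytest.raises(LedgerValidationError):
            write_ledger(led, tmp_path / "x.csv", "csv")


money_2dp = st.decimals(min_value=0, max_value=10**6, places=2)
fractions = st.decimals(min_value=Decimal("0.01"), max_value=1, places=2)


@st.composite
def ledgers(draw):
    n = draw(st.integers(min_value=0, max_value=12))
    items = []
    for i in range(n):
        phase = draw(st.sampled_from(["development", "pretest", "training",
                                      "delivery"]))
        capital = draw(st.booleans())
        per_patient = draw(st.booleans()) if phase == "delivery" else False
        items.append(CostItem(
            item_id=f"it{i}",
            label=draw(st.text(
                alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                max_size=20)),
            phase=phase,
            cost_class="capital" if capital else "recurrent",
            cost_behavior=draw(st.sampled_from(["fixed", "variable"])),
            unit_price=draw(money_2dp),
            quantity=draw(st.integers(min_value=1, max_value=20)),
            useful_life_years=float(draw(st.integers(1, 15))) if capital else None,
            apportionment_fraction=draw(fractions),
            minutes_per_patient=(draw(st.floats(0.5, 60)) if phase == "delivery"
                                 and draw(st.booleans()) else None),
            per_patient=per_patient,
        ))
    return CostLedger(items=items,
                      discount_rate=draw(st.floats(0, 0.2)),
                      cohort_size=draw(st.integers(1, 500)),
                      exchange_rate=draw(st.floats(50, 90)))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(led=ledgers(), fmt=st.sampled_from(["csv", "json"]))
def test_round_trip_is_identity(led, fmt, tmp_path_factory):
    """write_ledger then read_ledger is the identity on valid ledgers."""
    path = tmp_path_factory.mktemp("rt") / f"l.{fmt}"
    write_ledger(led, path, fmt)
    assert read_ledger(path, fmt) == led


def test_large_synthetic_ledger_round_trips(tmp_path):
    items = [item(f"i{k}", phase="delivery", price=str(k + 1),
                  per_patient=True) for k in range(1000)]
    led = CostLedger(items=items)
    path = tmp_path / "big.csv"
    write_ledger(led, path, "csv")
    assert read_ledger(path) == led


def test_fixture_function_is_fresh_each_call():
    a, b = table2_fixture(), table2_fixture()
    assert a == b and a is not b
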