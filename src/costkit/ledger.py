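"""Cost-ledger data model and I/O.

A :class:`CostLedger` is the single input object of every analysis in this
package: an ordered list of priced resource lines (:class:`CostItem`) plus
the handful of global parameters a costing study fixes up front (discount
rate, patient denominator, exchange rate, annual operational minutes).

The built-in :func:`table2_fixture` encodes the published cost table of a
tobacco-cessation intervention delivered in two district NCD clinics in
Punjab, India: four development-phase lines, one pretest, one training
total, and five per-patient delivery components. All headline outputs of
the package (unit cost 272 INR/patient, scale-up scenario grids, the
sensitivity range) derive from it.

Ledgers read and write as CSV (global parameters in ``#``-prefixed header
lines, items as rows) and as JSON (one object, field names identical).
Money serializes at two decimal places; Indian digit grouping ("4,91,040")
is accepted on input and never emitted.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Literal

import pandas as pd

from ._money import D, fmt_fraction, fmt_money, parse_money
from .errors import FormatError, LedgerValidationError

PHASES = ("development", "pretest", "training", "delivery")
COST_CLASSES = ("capital", "recurrent")
COST_BEHAVIORS = ("fixed", "variable")

# default annual operational time of a facility resource:
# 240 working days/year x 480 minutes/day
DEFAULT_ANNUAL_MINUTES = 240 * 480

_CSV_COLUMNS = [
    "item_id", "label", "phase", "cost_class", "cost_behavior",
    "unit_price", "quantity", "useful_life_years",
    "apportionment_fraction", "minutes_per_patient", "per_patient",
]


@dataclass
class CostItem:
    """One priced resource line.

    Parameters
    ----------
    item_id : short unique identifier.
    label : free-text description as it would appear in a report.
    phase : one of development / pretest / training / delivery.
    cost_class : capital (durable good with a useful life) or recurrent.
    cost_behavior : fixed or variable with patient volume.
    unit_price : money in INR. For ``per_patient`` items this is already a
        per-patient figure; for salaried-staff delivery lines it is the
        gross *monthly* salary; for capital lines the purchase price.
    quantity : number of units (e.g. staff holding the role).
    useful_life_years : capital items only — years over which the purchase
        is annualized.
    apportionment_fraction : share of a pooled resource attributable to
        the intervention, in (0, 1].
    minutes_per_patient : delivery items only — minutes of this resource
        (staff contact time or equipment use) consumed per patient.
    per_patient : True if ``unit_price`` is already expressed per patient
        served, short-circuiting any annualization/per-minute resolution.
    """

    item_id: str
    label: str
    phase: str
    cost_class: str
    cost_behavior: str
    unit_price: Decimal
    quantity: int = 1
    useful_life_years: float | None = None
    apportionment_fraction: Decimal = Decimal("1")
    minutes_per_patient: float | None = None
    per_patient: bool = False

    def __post_init__(self) -> None:
        self.phase = str(self.phase).strip().lower()
        self.cost_class = str(self.cost_class).strip().lower()
        self.cost_behavior = str(self.cost_behavior).strip().lower()
        self.unit_price = D(self.unit_price)
        self.quantity = int(self.quantity)
        self.apportionment_fraction = D(self.apportionment_fraction)
        if self.useful_life_years is not None:
            self.useful_life_years = float(self.useful_life_years)
        if self.minutes_per_patient is not None:
            self.minutes_per_patient = float(self.minutes_per_patient)
        self.per_patient = bool(self.per_patient)

    def ledger_cost(self) -> Decimal:
        """Apportioned financial cost of the line: price x quantity x fraction."""
        return self.unit_price * self.quantity * self.apportionment_fraction


@dataclass
class CostLedger:
    """Ordered collection of cost items plus study-level parameters."""

    items: list[CostItem] = field(default_factory=list)
    discount_rate: float = 0.03
    cohort_size: int = 100
    exchange_rate: float = 74.0
    annual_operational_minutes: float = DEFAULT_ANNUAL_MINUTES

    def by_phase(self, phase: str) -> list[CostItem]:
        return [it for it in self.items if it.phase == phase]

    def get(self, item_id: str) -> CostItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


@dataclass
class Issue:
    item_id: str | None
    severity: Literal["error", "warning"]
    message: str


@dataclass
class ValidationReport:
    ok: bool
    issues: list[Issue] = field(default_factory=list)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]


def validate_ledger(ledger: CostLedger) -> ValidationReport:
    """Check every ledger invariant; violations come back as the report,
    never as exceptions (``ok`` is False iff any error-severity issue)."""
    issues: list[Issue] = []

    def err(item_id, msg):
        issues.append(Issue(item_id, "error", msg))

    seen: set[str] = set()
    for it in ledger.items:
        if it.item_id in seen:
            err(it.item_id, "duplicate item_id")
        seen.add(it.item_id)
        if it.phase not in PHASES:
            err(it.item_id, f"unknown phase {it.phase!r}")
        if it.cost_class not in COST_CLASSES:
            err(it.item_id, f"unknown cost_class {it.cost_class!r}")
        if it.cost_behavior not in COST_BEHAVIORS:
            err(it.item_id, f"unknown cost_behavior {it.cost_behavior!r}")
        if it.unit_price < 0:
            err(it.item_id, "unit_price must be >= 0")
        if it.quantity < 1:
            err(it.item_id, "quantity must be >= 1")
        if not (0 < it.apportionment_fraction <= 1):
            err(it.item_id, "apportionment_fraction must be in (0, 1]")
        if it.cost_class == "capital" and not it.per_patient \
                and it.useful_life_years is None:
            err(it.item_id, "useful_life_years required for capital items")
        if it.useful_life_years is not None:
            if it.cost_class != "capital":
                err(it.item_id, "useful_life_years only valid on capital items")
            elif it.useful_life_years < 1:
                err(it.item_id, "useful_life_years must be >= 1")
        if it.minutes_per_patient is not None and it.phase != "delivery":
            err(it.item_id, "minutes_per_patient only valid on delivery items")

    if not (0 <= ledger.discount_rate <= 0.2):
        err(None, "discount_rate must be in [0, 0.2]")
    if ledger.cohort_size < 1:
        err(None, "cohort_size must be >= 1")
    if ledger.exchange_rate <= 0:
        err(None, "exchange_rate must be > 0")
    if ledger.annual_operational_minutes <= 0:
        err(None, "annual_operational_minutes must be > 0")

    return ValidationReport(ok=not any(i.severity == "error" for i in issues),
                            issues=issues)


# ---------------------------------------------------------------------------
# serialization

def _item_to_record(it: CostItem) -> dict:
    return {
        "item_id": it.item_id,
        "label": it.label,
        "phase": it.phase,
        "cost_class": it.cost_class,
        "cost_behavior": it.cost_behavior,
        "unit_price": fmt_money(it.unit_price),
        "quantity": it.quantity,
        "useful_life_years": "" if it.useful_life_years is None
                             else repr(it.useful_life_years),
        "apportionment_fraction": fmt_fraction(it.apportionment_fraction),
        "minutes_per_patient": "" if it.minutes_per_patient is None
                               else repr(it.minutes_per_patient),
        "per_patient": "true" if it.per_patient else "false",
    }


def _record_to_item(rec: dict, row: int) -> CostItem:
    missing = [c for c in _CSV_COLUMNS if c not in rec]
    if missing:
        raise FormatError(f"row {row}: missing required field(s) {missing}")

    def opt_float(key):
        v = rec[key]
        if v is None or str(v).strip() == "":
            return None
        return float(v)

    try:
        per_patient = str(rec["per_patient"]).strip().lower()
        if per_patient not in ("true", "false", "1", "0", ""):
            raise ValueError(f"bad boolean {rec['per_patient']!r}")
        return CostItem(
            item_id=str(rec["item_id"]).strip(),
            label=str(rec["label"]),
            phase=str(rec["phase"]),
            cost_class=str(rec["cost_class"]),
            cost_behavior=str(rec["cost_behavior"]),
            unit_price=parse_money(str(rec["unit_price"])),
            quantity=int(str(rec["quantity"]).strip() or 1),
            useful_life_years=opt_float("useful_life_years"),
            apportionment_fraction=parse_money(
                str(rec["apportionment_fraction"])),
            minutes_per_patient=opt_float("minutes_per_patient"),
            per_patient=per_patient in ("true", "1"),
        )
    except (ValueError, InvalidOperation) as exc:
        raise FormatError(f"row {row}: {exc}") from exc


_GLOBAL_FIELDS = {
    "discount_rate": float,
    "cohort_size": int,
    "exchange_rate": float,
    "annual_operational_minutes": float,
}


def write_ledger(ledger: CostLedger, path, format: str = "csv") -> None:
    """Serialize a ledger; ``read_ledger`` on the output returns an equal
    ledger. The ledger must validate without errors."""
    report = validate_ledger(ledger)
    if not report.ok:
        msgs = "; ".join(f"{i.item_id}: {i.message}" for i in report.errors())
        raise LedgerValidationError(f"refusing to write invalid ledger: {msgs}")
    path = Path(path)
    if format == "csv":
        header = "".join(
            f"# {name}={getattr(ledger, name)!r}\n" for name in _GLOBAL_FIELDS
        )
        df = pd.DataFrame([_item_to_record(it) for it in ledger.items],
                          columns=_CSV_COLUMNS)
        path.write_text(header + df.to_csv(index=False), encoding="utf-8")
    elif format == "json":
        payload = {name: getattr(ledger, name) for name in _GLOBAL_FIELDS}
        payload["items"] = [_item_to_record(it) for it in ledger.items]
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ledger(path, format: str | None = None) -> CostLedger:
    """Read a ledger from CSV or JSON (format inferred from the suffix when
    not given). Item order is preserved; enum fields are normalized
    case-insensitively; duplicate item_ids raise."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"

    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = payload.get("items", [])
        globals_ = {k: _GLOBAL_FIELDS[k](payload[k])
                    for k in _GLOBAL_FIELDS if k in payload}
    elif format == "csv":
        lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
        globals_ = {}
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, _, value = text.partition("=")
                key = key.strip()
                if key in _GLOBAL_FIELDS:
                    globals_[key] = _GLOBAL_FIELDS[key](value.strip())
        body = "".join(lines[body_start:])
        if not body.strip():
            raise FormatError(f"{path}: no header row")
        df = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        records = df.to_dict(orient="records")
    else:
        raise ValueError(f"unknown format {format!r}")

    items = [_record_to_item(rec, row) for row, rec in enumerate(records, 1)]
    dup = {i.item_id for i in items if sum(j.item_id == i.item_id for j in items) > 1}
    if dup:
        raise LedgerValidationError(f"duplicate item_id(s): {sorted(dup)}")
    return CostLedger(items=items, **globals_)


# ---------------------------------------------------------------------------
# built-in fixture

def table2_fixture() -> CostLedger:
    """The published cost ledger of the NCD-clinic tobacco-cessation study.

    Development-phase lines hold financial totals from administrative
    records (top-down costing); delivery lines hold already-resolved
    per-patient component costs (bottom-up costing). The patient
    denominator is 100 — the per-clinic cohort implied by the published
    unit-cost divisions (1,34,002 / 1,340 and 6,59,444 / 6,594) — with
    200 patients enrolled across the two clinics.
    """
    def item(item_id, label, phase, cls, behavior, price, **kw):
        return CostItem(item_id=item_id, label=label, phase=phase,
                        cost_class=cls, cost_behavior=behavior,
                        unit_price=Decimal(price), **kw)

    items = [
        item("dev_meetings_civil_society", "Meetings with civil society (n = 2)",
             "development", "recurrent", "variable", "9396"),
        item("dev_workshop_program_manager", "Workshop with Program Manager (n = 1)",
             "development", "recurrent", "variable", "491040"),
        item("dev_meeting_program_manager", "Meeting with Program Manager (n = 1)",
             "development", "recurrent", "variable", "93795"),
        item("dev_advocacy_workshop", "Advocacy Workshop (n = 1)",
             "development", "recurrent", "variable", "53593"),
        item("pretest", "Cost of doing a pre-test",
             "pretest", "recurrent", "variable", "11620"),
        item("training_hcp", "Total Health System Cost of Training of HCP",
             "training", "recurrent", "variable", "134002"),
        # delivery components, each already a per-patient cost
        item("delivery_human_resource", "Human Resource",
             "delivery", "recurrent", "variable", "76", per_patient=True),
        item("delivery_capital", "Capital Cost (Building, Furniture, Equipment)",
             "delivery", "capital", "fixed", "26", per_patient=True),
        item("delivery_pamphlets", "Pamphlets (IEC)",
             "delivery", "recurrent", "variable", "10", per_patient=True),
        item("delivery_sms_calls", "SMS and Follow-up calls (HR)",
             "delivery", "recurrent", "fixed", "160", per_patient=True),
        item("delivery_phone_bill", "Dedicated Phone Bill",
             "delivery", "recurrent", "fixed", "0.15", per_patient=True),
    ]
    return CostLedger(items=items, discount_rate=0.03, cohort_size=100,
                      exchange_rate=74.0,
                      annual_operational_minutes=DEFAULT_ANNUAL_MINUTES)


__all__ = [
    "CostItem", "CostLedger", "Issue", "ValidationReport",
    "read_ledger", "write_ledger", "validate_ledger", "table2_fixture",
    "PHASES", "DEFAULT_ANNUAL_MINUTES",
]
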