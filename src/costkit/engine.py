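"""Aggregate a cost ledger into phase summaries and per-patient unit costs.

Two costing views coexist, mirroring standard practice:

* **top-down (financial)**: development, pretest and training lines carry
  administrative totals; :func:`phase_summary` sums them, attaches
  proportional shares, and divides by the patient cohort for a unit cost.
* **bottom-up (activity-based)**: delivery lines resolve to a per-patient
  cost — directly when already expressed per patient, otherwise through
  annualization → per-minute rate → minutes used per patient (capital), or
  gross salary → per-minute opportunity cost → contact minutes (staff).
  :func:`unit_delivery_cost` assembles the per-patient component breakdown.

Rounding conventions: reported costs round half-up to integer INR;
proportions and USD figures to 2 dp. Delivery-panel proportions are taken
against the *integer-rounded* total — the convention that reproduces every
published proportion this package is validated on (27.94 / 9.56 / 3.68 /
58.82 / 0.06 against 272, not 272.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from ._money import D, pct, round_half_up, TWO_DP
from .annualize import (AnnuityInputs, CostingConfig, StaffCostInputs,
                        annualize_capital, per_minute_cost,
                        staff_cost_per_patient)
from .errors import ConfigurationError, DomainError
from .ledger import CostItem, CostLedger


@dataclass(frozen=True)
class LineItem:
    item_id: str
    label: str
    cost: Decimal          # exact, pre-rounding
    proportion: Decimal    # percent, 2 dp


@dataclass(frozen=True)
class PhaseCostSummary:
    phase: str
    line_items: tuple[LineItem, ...]
    total: Decimal         # exact sum of line items
    total_reported: int    # half-up integer INR
    unit_cost: int         # total / cohort_size, half-up integer INR
    total_usd: Decimal     # 2 dp


@dataclass(frozen=True)
class UnitCostBreakdown:
    """Per-patient delivery cost split into named components."""
    components: tuple[LineItem, ...]
    total_per_patient: Decimal      # exact component sum
    total_reported: int             # half-up integer INR
    total_per_patient_usd: Decimal  # 2 dp, from the reported total

    def component(self, item_id: str) -> LineItem:
        for c in self.components:
            if c.item_id == item_id:
                return c
        raise ConfigurationError(f"no delivery component {item_id!r}")


def convert_currency(amount_inr, exchange_rate: float) -> Decimal:
    """INR → USD at the study exchange rate, 2 dp."""
    if exchange_rate <= 0:
        raise DomainError("exchange rate must be > 0")
    return (D(amount_inr) / D(exchange_rate)).quantize(TWO_DP)


def phase_summary(ledger: CostLedger, phase: str,
                  include_pretest: bool = False) -> PhaseCostSummary:
    """Top-down summary of one phase: line costs (price x quantity x
    apportionment), proportional shares against the exact phase total, and
    the per-patient unit cost. ``include_pretest`` folds the pretest lines
    into the development phase, matching how the published table totals
    them (the development figure excluding pretest is what the study's
    abstract reports)."""
    items = list(ledger.by_phase(phase))
    if phase == "development" and include_pretest:
        items += ledger.by_phase("pretest")
    costs = [(it, it.ledger_cost()) for it in items]
    total = sum((c for _, c in costs), Decimal(0))
    lines = tuple(
        LineItem(it.item_id, it.label, c, pct(c, total)) for it, c in costs
    )
    return PhaseCostSummary(
        phase=phase,
        line_items=lines,
        total=total,
        total_reported=round_half_up(total),
        unit_cost=round_half_up(total / ledger.cohort_size),
        total_usd=convert_currency(total, ledger.exchange_rate),
    )


def _resolve_delivery_item(it: CostItem, ledger: CostLedger,
                           config: CostingConfig) -> Decimal:
    """Per-patient cost of one delivery line."""
    if it.per_patient:
        return it.ledger_cost()
    if it.cost_class == "capital":
        if it.minutes_per_patient is None:
            raise ConfigurationError(
                f"delivery item {it.item_id!r}: capital line needs "
                "minutes_per_patient to resolve to a per-patient cost")
        annual = annualize_capital(
            AnnuityInputs(float(it.ledger_cost()), it.useful_life_years,
                          ledger.discount_rate),
            config=config)
        rate = per_minute_cost(annual, ledger.annual_operational_minutes)
        return D(rate * it.minutes_per_patient)
    if it.minutes_per_patient is not None:
        # salaried staff: unit_price is the gross monthly salary
        per_person = staff_cost_per_patient(StaffCostInputs(
            gross_salary_per_month=float(it.unit_price),
            working_days_per_month=config.working_days_per_month,
            working_minutes_per_day=config.working_minutes_per_day,
            minutes_per_patient=it.minutes_per_patient,
        ))
        return D(per_person * it.quantity * float(it.apportionment_fraction))
    raise ConfigurationError(
        f"delivery item {it.item_id!r} has neither a per-patient price nor "
        "a staff/capital resolution path (minutes_per_patient missing)")


def unit_delivery_cost(ledger: CostLedger,
                       config: CostingConfig | None = None) -> UnitCostBreakdown:
    """Bottom-up per-patient cost of service delivery.

    Components keep ledger order; the exact total is the plain sum; the
    reported total is half-up integer INR and is the denominator for the
    component proportions.
    """
    config = config or CostingConfig()
    comps = [(it, _resolve_delivery_item(it, ledger, config))
             for it in ledger.by_phase("delivery")]
    total = sum((v for _, v in comps), Decimal(0))
    reported = round_half_up(total)
    lines = tuple(
        LineItem(it.item_id, it.label, v, pct(v, Decimal(reported)))
        for it, v in comps
    )
    return UnitCostBreakdown(
        components=lines,
        total_per_patient=total,
        total_reported=reported,
        total_per_patient_usd=convert_currency(reported, ledger.exchange_rate),
    )


def render_report(summaries: list[PhaseCostSummary],
                  breakdown: UnitCostBreakdown | None = None,
                  exchange_rate: float = 74.0) -> str:
    """Deterministic plain-text cost table: one row per line item with
    INR cost, USD equivalent and proportional share."""
    w_label, w_cost, w_pct = 52, 24, 10
    header = (f"{'Cost Components of Intervention':<{w_label}}"
              f"{'Cost INR (USD)':>{w_cost}}{'Prop. %':>{w_pct}}")
    rule = "-" * len(header)
    out = [header, rule]

    def cost_cell(amount: Decimal) -> str:
        usd = convert_currency(amount, exchange_rate)
        # sub-rupee amounts keep 2 dp so they don't vanish to 0
        inr = round_half_up(amount) if abs(amount) >= 1 \
            else amount.quantize(TWO_DP)
        return f"{inr} ({usd})"

    for s in summaries:
        out.append(f"[{s.phase} phase]")
        for li in s.line_items:
            out.append(f"{li.label:<{w_label}}"
                       f"{cost_cell(li.cost):>{w_cost}}"
                       f"{li.proportion:>{w_pct}}")
        out.append(f"{'Total':<{w_label}}{cost_cell(s.total):>{w_cost}}"
                   f"{'100':>{w_pct}}")
        out.append(f"{'Unit Cost':<{w_label}}"
                   f"{cost_cell(Decimal(s.unit_cost)):>{w_cost}}")
        out.append(rule)
    if breakdown is not None:
        out.append("[unit cost of service delivery]")
        for li in breakdown.components:
            out.append(f"{li.label:<{w_label}}"
                       f"{cost_cell(li.cost):>{w_cost}}"
                       f"{li.proportion:>{w_pct}}")
        out.append(f"{'Overall Cost':<{w_label}}"
                   f"{cost_cell(Decimal(breakdown.total_reported)):>{w_cost}}"
                   f"{'100':>{w_pct}}")
        out.append(rule)
    return "\n".join(out) + "\n"


__all__ = [
    "LineItem", "PhaseCostSummary", "UnitCostBreakdown",
    "phase_summary", "unit_delivery_cost", "convert_currency", "render_report",
]
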