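"""Scale-up scenario models for the per-patient delivery cost.

Four scenarios, built with program managers in mind, probe how the unit
cost falls when the intervention is rolled out at scale:

1. **Group counseling** — components tied to one counseling contact
   (staff time, capital, the dedicated phone line) are shared across a
   disease-specific patient group, so their per-patient share divides by
   the group size; consumable/communication components stay per-patient.
2. **Bulk procurement** — pamphlets and the SMS/follow-up-call package
   are bought in bulk at a negotiated discount off the per-patient price.
3. **Integrated training** — provider training rides on routine in-service
   programs; the per-patient training cost falls by the integration saving.
4. **Cumulative** — group counseling and bulk procurement combined, with
   the training discount applied on top for a total per-patient figure.

On the built-in study ledger the shareable pool is 76 + 26 + 0.15 =
102.15 INR and the discountable pool 10 + 160 = 170 INR, which reproduces
every published scenario cell exactly under half-up integer rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from ._money import D, round_half_up
from .engine import UnitCostBreakdown
from .errors import ConfigurationError, DomainError


@dataclass(frozen=True)
class ScenarioConfig:
    """Which delivery components a scenario acts on.

    Defaults name the built-in study ledger's components; override both
    tuples for ledgers with different component ids.
    """
    shareable_component_ids: tuple[str, ...] = (
        "delivery_human_resource", "delivery_capital", "delivery_phone_bill")
    discountable_component_ids: tuple[str, ...] = (
        "delivery_pamphlets", "delivery_sms_calls")


DEFAULT_CONFIG = ScenarioConfig()


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str              # group | bulk | training | cumulative
    axis_value: float          # group size or discount fraction
    per_patient_cost: int      # half-up integer INR
    exact: Decimal             # pre-rounding per-patient figure
    components: dict = field(default_factory=dict, compare=False)


def _pools(breakdown: UnitCostBreakdown, config: ScenarioConfig):
    ids = {c.item_id for c in breakdown.components}
    for cid in (*config.shareable_component_ids,
                *config.discountable_component_ids):
        if cid not in ids:
            raise ConfigurationError(f"scenario component {cid!r} not in breakdown")
    share = sum((c.cost for c in breakdown.components
                 if c.item_id in config.shareable_component_ids), Decimal(0))
    disc = sum((c.cost for c in breakdown.components
                if c.item_id in config.discountable_component_ids), Decimal(0))
    rest = breakdown.total_per_patient - share - disc
    return share, disc, rest


def group_counseling_cost(breakdown: UnitCostBreakdown, group_size: int,
                          config: ScenarioConfig = DEFAULT_CONFIG) -> ScenarioResult:
    """Scenario 1: shareable components divided across a counseling group
    of ``group_size`` patients treated as a single service unit."""
    if group_size < 1:
        raise DomainError("group size must be >= 1")
    share, disc, rest = _pools(breakdown, config)
    exact = disc + rest + share / group_size
    return ScenarioResult("group", group_size, round_half_up(exact), exact,
                          {"shareable": share, "non_shareable": disc + rest})


def bulk_discount_cost(breakdown: UnitCostBreakdown, discount: float,
                       config: ScenarioConfig = DEFAULT_CONFIG) -> ScenarioResult:
    """Scenario 2: discountable components reduced by a bulk-procurement
    ``discount`` fraction in [0, 1)."""
    if not (0 <= discount < 1):
        raise DomainError("discount must be in [0, 1)")
    _, disc, _ = _pools(breakdown, config)
    exact = breakdown.total_per_patient - D(discount) * disc
    return ScenarioResult("bulk", discount, round_half_up(exact), exact,
                          {"discountable": disc})


def training_discount_cost(unit_training_cost, discount: float) -> ScenarioResult:
    """Scenario 3: per-patient training cost when sessions are integrated
    into routine in-service programs, abstracted as a discount fraction."""
    if not (0 <= discount < 1):
        raise DomainError("discount must be in [0, 1)")
    base = D(unit_training_cost)
    if base < 0:
        raise DomainError("training cost must be >= 0")
    exact = base * (1 - D(discount))
    return ScenarioResult("training", discount, round_half_up(exact), exact)


def cumulative_scenario(breakdown: UnitCostBreakdown, unit_training_cost,
                        group_size: int, discount: float,
                        config: ScenarioConfig = DEFAULT_CONFIG,
                        ) -> tuple[ScenarioResult, ScenarioResult]:
    """Scenario 4: group counseling and bulk discount together, plus the
    discounted training cost.

    Returns ``(implementation, total_with_training)``; the total is the
    sum of the two independently rounded figures, matching how the study
    tabulates it.
    """
    if group_size < 1:
        raise DomainError("group size must be >= 1")
    if not (0 <= discount < 1):
        raise DomainError("discount must be in [0, 1)")
    share, disc, rest = _pools(breakdown, config)
    exact = share / group_size + (1 - D(discount)) * disc + rest
    implementation = ScenarioResult("cumulative", group_size,
                                    round_half_up(exact), exact,
                                    {"group_size": group_size,
                                     "discount": discount})
    training = training_discount_cost(unit_training_cost, discount)
    total = ScenarioResult(
        "cumulative", group_size,
        implementation.per_patient_cost + training.per_patient_cost,
        implementation.exact + training.exact,
        {"implementation": implementation.per_patient_cost,
         "training": training.per_patient_cost})
    return implementation, total


def scenario_grid(breakdown: UnitCostBreakdown, unit_training_cost,
                  group_sizes=(5, 10, 15, 20),
                  discounts=(0.10, 0.20, 0.30, 0.40),
                  config: ScenarioConfig = DEFAULT_CONFIG) -> dict:
    """All four scenarios over the published grids, as plain dicts keyed
    by axis value — the shape the scenario table prints."""
    return {
        "group": {g: group_counseling_cost(breakdown, g, config).per_patient_cost
                  for g in group_sizes},
        "bulk": {d: bulk_discount_cost(breakdown, d, config).per_patient_cost
                 for d in discounts},
        "training": {d: training_discount_cost(unit_training_cost, d).per_patient_cost
                     for d in discounts},
        "cumulative": {
            "minimal": [r.per_patient_cost for r in cumulative_scenario(
                breakdown, unit_training_cost, min(group_sizes), min(discounts), config)],
            "optimistic": [r.per_patient_cost for r in cumulative_scenario(
                breakdown, unit_training_cost, max(group_sizes), max(discounts), config)],
        },
    }


__all__ = [
    "ScenarioConfig", "ScenarioResult", "DEFAULT_CONFIG",
    "group_counseling_cost", "bulk_discount_cost", "training_discount_cost",
    "cumulative_scenario", "scenario_grid",
]
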