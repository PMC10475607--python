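"""Randomized cost ledgers with analytically known ground truth.

The generator emulates the resource structure of a facility-based
behavioral intervention: development/pretest/training lines with financial
totals, and a delivery phase mixing capital goods (purchase price, useful
life, minutes of use per patient), salaried staff roles (gross monthly
salary, contact minutes per patient), and per-patient consumables /
communication items. Prices are drawn log-uniformly, mirroring the span of
real cost tables (sub-rupee phone-bill shares up to lakh-scale workshops).

Every ledger ships with a :class:`GroundTruth` computed at generation time
by *separate* arithmetic: annuity factors come from an explicit
discount-sum loop (not the closed form the costing engine uses), staff and
scenario figures from inline formulas, sums from plain float addition. The
pipeline must then recover these values, which makes the generator an
independent oracle for the costing engine, the scenario models and the
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .annualize import CostingConfig
from .engine import unit_delivery_cost
from .errors import DomainError
from .ledger import CostItem, CostLedger, validate_ledger
from .scenarios import (ScenarioConfig, bulk_discount_cost,
                        group_counseling_cost)
from .sensitivity import DSAParameter, one_way_dsa


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_capital_items: int = 3
    n_staff_roles: int = 2
    n_consumables: int = 3
    n_development_items: int = 3
    n_training_items: int = 1
    price_range: tuple[float, float] = (500.0, 500_000.0)   # capital/phase lines
    consumable_range: tuple[float, float] = (0.10, 200.0)   # per-patient prices
    salary_range: tuple[float, float] = (20_000.0, 120_000.0)  # per month
    life_range: tuple[int, int] = (1, 10)
    minutes_range: tuple[float, float] = (2.0, 30.0)
    cohort_size: int = 100
    discount_rate: float = 0.03
    group_sizes: tuple[int, ...] = (5, 10, 15, 20)
    bulk_discounts: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)

    def check(self) -> None:
        for name in ("price_range", "consumable_range", "salary_range",
                     "life_range", "minutes_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi) or hi <= 0:
                raise DomainError(f"degenerate {name}: ({lo}, {hi})")
        if min(self.n_capital_items, self.n_staff_roles, self.n_consumables,
               self.n_development_items, self.n_training_items) < 0:
            raise DomainError("item counts must be >= 0")
        if self.cohort_size < 1:
            raise DomainError("cohort_size must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Exact pre-rounding expectations for a generated ledger."""
    unit_delivery_cost: float
    component_costs: dict[str, float]          # item_id -> per-patient cost
    phase_totals: dict[str, float]             # development/pretest/training
    shareable_ids: tuple[str, ...]             # capital + staff components
    discountable_ids: tuple[str, ...]          # consumable components
    group_scenario: dict[int, float]           # group size -> exact cost
    bulk_scenario: dict[float, float]          # discount -> exact cost

    @property
    def scenario_config(self) -> ScenarioConfig:
        return ScenarioConfig(shareable_component_ids=self.shareable_ids,
                              discountable_component_ids=self.discountable_ids)


def _loop_annuity(rate: float, life: int) -> float:
    # deliberate brute-force present-value sum, independent of the
    # closed-form annuity factor used by the costing engine
    return float(life) if rate == 0 else sum(
        (1.0 + rate) ** (-t) for t in range(1, life + 1))


def generate_ledger(config: SynthConfig,
                    costing: CostingConfig | None = None,
                    ) -> tuple[CostLedger, GroundTruth]:
    """Draw a random ledger and its analytic ground truth. Deterministic
    given ``config.seed``; the returned ledger always validates."""
    config.check()
    costing = costing or CostingConfig()
    rng = np.random.default_rng(config.seed)
    annual_minutes = costing.annual_operational_minutes

    def log_uniform(lo, hi):
        return round(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))), 2)

    items: list[CostItem] = []
    component_costs: dict[str, float] = {}
    phase_totals = {"development": 0.0, "pretest": 0.0, "training": 0.0}

    for phase, count in (("development", config.n_development_items),
                         ("training", config.n_training_items)):
        for i in range(count):
            price = log_uniform(*config.price_range)
            items.append(CostItem(
                item_id=f"{phase}_{i}", label=f"{phase} line {i}",
                phase=phase, cost_class="recurrent", cost_behavior="variable",
                unit_price=Decimal(f"{price:.2f}")))
            phase_totals[phase] += price

    shareable: list[str] = []
    discountable: list[str] = []

    for i in range(config.n_capital_items):
        price = log_uniform(*config.price_range)
        life = int(rng.integers(config.life_range[0], config.life_range[1] + 1))
        minutes = round(float(rng.uniform(*config.minutes_range)), 2)
        frac = float(rng.choice([0.25, 0.5, 0.75, 1.0]))
        iid = f"capital_{i}"
        items.append(CostItem(
            item_id=iid, label=f"capital good {i}", phase="delivery",
            cost_class="capital", cost_behavior="fixed",
            unit_price=Decimal(f"{price:.2f}"), useful_life_years=life,
            apportionment_fraction=Decimal(str(frac)),
            minutes_per_patient=minutes))
        # truth: apportioned price -> annual charge via loop-summed annuity
        # -> per-minute rate -> minutes of use per patient
        annual = price * frac / _loop_annuity(config.discount_rate, life)
        component_costs[iid] = annual / annual_minutes * minutes
        shareable.append(iid)

    for i in range(config.n_staff_roles):
        salary = log_uniform(*config.salary_range)
        minutes = round(float(rng.uniform(*config.minutes_range)), 2)
        iid = f"staff_{i}"
        items.append(CostItem(
            item_id=iid, label=f"staff role {i}", phase="delivery",
            cost_class="recurrent", cost_behavior="variable",
            unit_price=Decimal(f"{salary:.2f}"),
            minutes_per_patient=minutes))
        per_min = salary / (costing.working_days_per_month
                            * costing.working_minutes_per_day)
        component_costs[iid] = per_min * minutes
        shareable.append(iid)

    for i in range(config.n_consumables):
        price = log_uniform(*config.consumable_range)
        iid = f"consumable_{i}"
        items.append(CostItem(
            item_id=iid, label=f"consumable {i}", phase="delivery",
            cost_class="recurrent", cost_behavior="variable",
            unit_price=Decimal(f"{price:.2f}"), per_patient=True))
        component_costs[iid] = price
        discountable.append(iid)

    unit_cost = sum(component_costs.values())
    share_sum = sum(component_costs[i] for i in shareable)
    disc_sum = sum(component_costs[i] for i in discountable)
    rest = unit_cost - share_sum - disc_sum

    truth = GroundTruth(
        unit_delivery_cost=unit_cost,
        component_costs=component_costs,
        phase_totals=phase_totals,
        shareable_ids=tuple(shareable),
        discountable_ids=tuple(discountable),
        group_scenario={g: disc_sum + rest + share_sum / g
                        for g in config.group_sizes},
        bulk_scenario={d: unit_cost - d * disc_sum
                       for d in config.bulk_discounts},
    )
    ledger = CostLedger(items=items, discount_rate=config.discount_rate,
                        cohort_size=config.cohort_size,
                        annual_operational_minutes=annual_minutes)
    report = validate_ledger(ledger)
    assert report.ok, report.issues
    return ledger, truth


@dataclass
class RecoveryReport:
    n_pass: int = 0
    n_fail: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.n_fail == 0


def recovery_suite(n_seeds: int, base_config: SynthConfig | None = None,
                   rtol: float = 1e-9) -> RecoveryReport:
    """Run the full pipeline on ``n_seeds`` generated ledgers and check
    every stage against the analytic ground truth: unit-cost and
    per-component recovery, scenario closed forms, group-size
    monotonicity, and the 0.4 x component DSA range identity."""
    if n_seeds < 1:
        raise DomainError("n_seeds must be >= 1")
    base = base_config or SynthConfig()
    report = RecoveryReport()

    def close(a, b):
        return abs(float(a) - float(b)) <= rtol * max(1.0, abs(float(b)))

    for seed in range(n_seeds):
        config = SynthConfig(**{**base.__dict__, "seed": seed})
        ledger, truth = generate_ledger(config)
        failures = []

        bd = unit_delivery_cost(ledger)
        if not close(bd.total_per_patient, truth.unit_delivery_cost):
            failures.append("unit cost mismatch")
        for c in bd.components:
            if not close(c.cost, truth.component_costs[c.item_id]):
                failures.append(f"component {c.item_id} mismatch")

        scfg = truth.scenario_config
        for g, expect in truth.group_scenario.items():
            if not close(group_counseling_cost(bd, g, scfg).exact, expect):
                failures.append(f"group scenario g={g} mismatch")
        for d, expect in truth.bulk_scenario.items():
            if not close(bulk_discount_cost(bd, d, scfg).exact, expect):
                failures.append(f"bulk scenario d={d} mismatch")

        grid = [group_counseling_cost(bd, g, scfg).exact
                for g in sorted(truth.group_scenario)]
        if any(a < b for a, b in zip(grid, grid[1:])):
            failures.append("group scenario not monotone decreasing")

        if truth.discountable_ids:
            params = [DSAParameter(name=i, target=i)
                      for i in truth.discountable_ids]
            dsa = one_way_dsa(ledger, params, breakdown=bd)
            for e in dsa.entries:
                expect = 0.4 * truth.component_costs[e.name]
                if not close(e.range_exact, expect):
                    failures.append(f"DSA range for {e.name} mismatch")

        if failures:
            report.n_fail += 1
            report.failures.extend(f"seed {seed}: {m}" for m in failures)
        else:
            report.n_pass += 1
    return report


__all__ = ["SynthConfig", "GroundTruth", "RecoveryReport",
           "generate_ledger", "recovery_suite"]
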