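"""Capital annualization, per-minute costing and staff opportunity cost.

Capital goods are converted to an equivalent annual cost with the standard
health-economics annuity method: a purchase of price P with useful life L
years at annual discount rate r costs

    P / A(r, L),     A(r, L) = (1 - (1+r)^(-L)) / r     (A(0, L) = L)

per year, where A is the present value of one currency unit per year for L
years with payments in arrears. Re-discounting that annual stream over the
life recovers P exactly. A straight-line alternative (P / L) is available
behind a flag for comparison.

Annual costs convert to per-minute rates over the facility's operational
time, and salaried staff time is valued at opportunity cost from the gross
salary and the minutes dedicated per patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class CostingConfig:
    """Working-time and method settings shared by the costing operations.

    The defaults — 240 working days/year of 480 minutes (115,200
    operational minutes/year), 20 working days/month — are conventional
    public-facility assumptions; every result that depends on them is
    config-sensitive and they are exposed here rather than hard-coded.
    """

    working_days_per_year: int = 240
    working_minutes_per_day: int = 480
    working_days_per_month: int = 20
    straight_line: bool = False  # straight-line (price/life) instead of annuity

    @property
    def annual_operational_minutes(self) -> float:
        return self.working_days_per_year * self.working_minutes_per_day


@dataclass(frozen=True)
class AnnuityInputs:
    purchase_price: float
    useful_life_years: float
    discount_rate: float = 0.03


@dataclass(frozen=True)
class StaffCostInputs:
    gross_salary_per_month: float
    working_days_per_month: float
    working_minutes_per_day: float
    minutes_per_patient: float


def annuity_factor(rate: float, life: float) -> float:
    """Present value of a unit annual payment for ``life`` years at
    ``rate``, payments in arrears; equals ``life`` when the rate is zero.

    Strictly increasing in life, strictly decreasing in rate.
    """
    if life < 1:
        raise DomainError(f"useful life must be >= 1 year, got {life}")
    if rate < 0:
        raise DomainError(f"discount rate must be >= 0, got {rate}")
    if rate == 0:
        return float(life)
    # log1p/expm1 keep precision (and the L limit) as rate -> 0
    return -math.expm1(-life * math.log1p(rate)) / rate


def annualize_capital(inputs: AnnuityInputs, *,
                      config: CostingConfig | None = None) -> float:
    """Equivalent annual cost of a capital purchase over its useful life.

    Dividing the price by the annuity factor makes the discounted stream
    of annual charges sum back to the purchase price.
    """
    if inputs.purchase_price < 0:
        raise DomainError("purchase price must be >= 0")
    if config is not None and config.straight_line:
        if inputs.useful_life_years < 1:
            raise DomainError("useful life must be >= 1 year")
        return inputs.purchase_price / inputs.useful_life_years
    return inputs.purchase_price / annuity_factor(inputs.discount_rate,
                                                  inputs.useful_life_years)


def per_minute_cost(annual_cost: float, annual_operational_minutes: float) -> float:
    """Annual cost spread over the minutes a resource is available for
    service delivery in a year."""
    if annual_operational_minutes <= 0:
        raise DomainError("annual operational minutes must be > 0")
    return annual_cost / annual_operational_minutes


def staff_cost_per_patient(inputs: StaffCostInputs) -> float:
    """Opportunity cost of staff contact time per patient: the per-minute
    gross salary times minutes dedicated to one patient."""
    if inputs.gross_salary_per_month <= 0:
        raise DomainError("gross salary must be > 0")
    if inputs.working_days_per_month <= 0 or inputs.working_minutes_per_day <= 0:
        raise DomainError("working time must be > 0")
    if inputs.minutes_per_patient < 0:
        raise DomainError("minutes per patient must be >= 0")
    per_minute = inputs.gross_salary_per_month / (
        inputs.working_days_per_month * inputs.working_minutes_per_day)
    return per_minute * inputs.minutes_per_patient


def apportion(total_cost, fraction):
    """Share of a pooled resource attributable to one use. Fractions over
    users of the resource that sum to 1 conserve the total exactly."""
    if not (0 <= fraction <= 1):
        raise DomainError(f"apportionment fraction must be in [0, 1], got {fraction}")
    return total_cost * fraction


__all__ = [
    "CostingConfig", "AnnuityInputs", "StaffCostInputs",
    "annuity_factor", "annualize_capital", "per_minute_cost",
    "staff_cost_per_patient", "apportion",
]
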