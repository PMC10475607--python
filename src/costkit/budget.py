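"""Multi-year budget-impact projection for one clinic.

Projects the payer's total program cost over a horizon (default 10 years):
an initial provider training in year 1, refresher trainings at a fixed
interval thereafter, and delivery of the intervention to a constant annual
patient load at the per-patient unit cost. Costs are booked at the start
of each year, so year t discounts by (1 + r)^-(t-1) — year 1 is
undiscounted; the convention is explicit here and the discount rate is a
config field, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class BIAConfig:
    """Budget-impact inputs.

    annual_patients : patients served per clinic per year (current
        capacity utilization).
    unit_delivery_cost : per-patient delivery cost, INR.
    initial_training_cost : one-off training cost incurred in year 1.
    refresher_training_cost : cost of each refresher session.
    refresher_interval_years : years between refreshers (program
        operational guidelines set the frequency; it is an input here).
    """
    annual_patients: int
    unit_delivery_cost: float
    initial_training_cost: float = 0.0
    refresher_training_cost: float = 0.0
    refresher_interval_years: int = 1
    horizon_years: int = 10
    discount_rate: float = 0.03


@dataclass(frozen=True)
class YearCost:
    year: int
    training: float
    delivery: float
    total: float
    discounted_total: float


@dataclass(frozen=True)
class BIAResult:
    yearly: tuple[YearCost, ...]
    undiscounted_sum: float
    discounted_sum: float


def project_costs(config: BIAConfig) -> BIAResult:
    """Year-by-year cost projection with present-value totals."""
    if config.horizon_years < 1:
        raise DomainError("horizon must be >= 1 year")
    if config.refresher_interval_years < 1:
        raise DomainError("refresher interval must be >= 1 year")
    if config.annual_patients < 0 or config.discount_rate < 0:
        raise DomainError("patients and discount rate must be >= 0")
    if min(config.unit_delivery_cost, config.initial_training_cost,
           config.refresher_training_cost) < 0:
        raise DomainError("costs must be >= 0")

    yearly = []
    for t in range(1, config.horizon_years + 1):
        if t == 1:
            training = config.initial_training_cost
        elif (t - 1) % config.refresher_interval_years == 0:
            training = config.refresher_training_cost
        else:
            training = 0.0
        delivery = config.annual_patients * config.unit_delivery_cost
        total = training + delivery
        discounted = total / (1.0 + config.discount_rate) ** (t - 1)
        yearly.append(YearCost(t, training, delivery, total, discounted))

    return BIAResult(
        yearly=tuple(yearly),
        undiscounted_sum=sum(y.total for y in yearly),
        discounted_sum=sum(y.discounted_total for y in yearly),
    )


__all__ = ["BIAConfig", "BIAResult", "YearCost", "project_costs"]
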