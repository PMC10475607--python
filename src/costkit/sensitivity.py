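"""One-way deterministic sensitivity analysis with tornado ranking.

Each parameter is varied alone between a low and a high bound — explicit
bounds when known, otherwise the conventional ±20% spread around the base
value — while every other input stays at base, and the per-patient
delivery cost is recomputed at both ends. Parameters may target a single
delivery component (additive perturbation of that component) or the
overall package cost (multiplicative factor on the reported total, which
is how an aggregate "everything moves together" uncertainty is modelled).
Ranking the absolute output ranges in decreasing order gives the tornado
ordering; ties break lexicographically on the parameter name so output is
deterministic.

With symmetric ±20% bounds on an additively entering component, the output
range is exactly 0.4 x the component's base value before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from ._money import D, round_half_up
from .annualize import CostingConfig
from .engine import UnitCostBreakdown, unit_delivery_cost
from .errors import ConfigurationError, DomainError
from .ledger import CostLedger

#: target name addressing the overall package cost rather than a component
TOTAL = "total"

DEFAULT_SPREAD = 0.20


@dataclass(frozen=True)
class DSAParameter:
    """One input varied in the analysis.

    ``target`` is a delivery-component item_id, or :data:`TOTAL` for the
    overall package cost. ``base_value`` defaults to the component's base
    cost (or the rounded package total); explicit ``low``/``high`` bounds
    override the symmetric ``spread``.
    """
    name: str
    target: str = TOTAL
    base_value: Decimal | None = None
    low: Decimal | None = None
    high: Decimal | None = None
    spread: float = DEFAULT_SPREAD


@dataclass(frozen=True)
class DSAEntry:
    name: str
    output_low: int
    output_high: int
    output_low_exact: Decimal
    output_high_exact: Decimal

    @property
    def range(self) -> int:
        return abs(self.output_high - self.output_low)

    @property
    def range_exact(self) -> Decimal:
        return abs(self.output_high_exact - self.output_low_exact)


@dataclass(frozen=True)
class DSAResult:
    entries: tuple[DSAEntry, ...]
    base_output: int
    overall_min: int
    overall_max: int
    ranking: tuple[str, ...] = field(default=())


def resolve_bounds(param: DSAParameter,
                   base_value: Decimal | None = None) -> tuple[Decimal, Decimal]:
    """Low/high bounds for a parameter: explicit bounds pass through,
    otherwise base x (1 - spread) and base x (1 + spread)."""
    base = D(base_value) if base_value is not None else param.base_value
    if param.low is not None and param.high is not None:
        low, high = D(param.low), D(param.high)
        if low > high:
            raise DomainError(f"{param.name}: low bound {low} > high bound {high}")
        return low, high
    if base is None:
        raise ConfigurationError(f"{param.name}: no base value to spread around")
    if base < 0:
        raise DomainError(f"{param.name}: base value must be >= 0")
    s = D(param.spread)
    return base * (1 - s), base * (1 + s)


def one_way_dsa(ledger: CostLedger, params: list[DSAParameter],
                config: CostingConfig | None = None,
                breakdown: UnitCostBreakdown | None = None) -> DSAResult:
    """Recompute the per-patient delivery cost at each parameter's low and
    high bound, all other inputs at base."""
    if breakdown is None:
        breakdown = unit_delivery_cost(ledger, config)
    base_total = breakdown.total_per_patient
    base_reported = breakdown.total_reported
    component_base = {c.item_id: c.cost for c in breakdown.components}

    entries = []
    for p in params:
        if p.target == TOTAL:
            base = D(p.base_value) if p.base_value is not None \
                else Decimal(base_reported)
            low, high = resolve_bounds(p, base)
            out_low, out_high = low, high
        else:
            if p.target not in component_base:
                raise ConfigurationError(
                    f"DSA parameter {p.name!r} targets unknown component "
                    f"{p.target!r}")
            base = D(p.base_value) if p.base_value is not None \
                else component_base[p.target]
            low, high = resolve_bounds(p, base)
            out_low = base_total - component_base[p.target] + low
            out_high = base_total - component_base[p.target] + high
        entries.append(DSAEntry(p.name, round_half_up(out_low),
                                round_half_up(out_high), out_low, out_high))

    if not entries:
        return DSAResult((), base_reported, base_reported, base_reported, ())
    ranking = tuple(e.name for e in
                    sorted(entries, key=lambda e: (-e.range_exact, e.name)))
    return DSAResult(
        entries=tuple(entries),
        base_output=base_reported,
        overall_min=min(min(e.output_low, e.output_high) for e in entries),
        overall_max=max(max(e.output_low, e.output_high) for e in entries),
        ranking=ranking,
    )


def tornado_table(result: DSAResult, top_n: int = 5) -> list[DSAEntry]:
    """Entries sorted by descending output range (lexicographic
    tie-break), truncated to the ``top_n`` most influential parameters."""
    if top_n < 1:
        raise DomainError("top_n must be >= 1")
    by_name = {e.name: e for e in result.entries}
    return [by_name[name] for name in result.ranking[:top_n]]


def tornado_plot(result: DSAResult, path, top_n: int = 5) -> None:
    """Horizontal-bar tornado diagram of the DSA, widest bar on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = tornado_table(result, top_n)
    names = [e.name for e in rows][::-1]
    lows = [min(e.output_low, e.output_high) for e in rows][::-1]
    widths = [e.range for e in rows][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(rows), 3) + 1))
    ax.barh(names, widths, left=lows, color="#4878b0")
    ax.axvline(result.base_output, color="k", lw=1, ls="--",
               label=f"base {result.base_output}")
    ax.set_xlabel("per-patient delivery cost (INR)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "TOTAL", "DEFAULT_SPREAD", "DSAParameter", "DSAEntry", "DSAResult",
    "resolve_bounds", "one_way_dsa", "tornado_table", "tornado_plot",
]
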