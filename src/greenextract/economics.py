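"""Cost-benefit balance of a solvent substitution, in EUR per tonne of seeds.

Costs: solvent make-up (consumption times the price difference) and extra
steam.  Benefits: the value of shifting product mass from cake to oil (only
the recoverable-value share of the gross extra oil is credited) and a fixed
cost reduction from the capacity gain.  Line items are reported at the
granularity used in practice (make-up to the unit, the rest to one decimal);
full precision is retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .energy import round_half_up

__all__ = [
    "EconomicAssumptions",
    "BalanceLine",
    "EconomicBalance",
    "solvent_makeup_cost",
    "steam_cost",
    "oil_shift_benefit",
    "balance",
]


@dataclass
class EconomicAssumptions:
    """Prices and consumptions of the substitution scenario.

    Prices in EUR/kg (solvent) and EUR/t (steam, oil, cake); consumptions per
    tonne of crushed seeds.
    """

    solvent_price_alt: float = 5.0  # EUR/kg
    solvent_price_ref: float = 0.9
    solvent_consumption: float = 0.75  # kg/t seeds
    extra_steam: float = 37.0  # kg/t seeds
    steam_price: float = 30.0  # EUR/t
    extra_oil_gross: float = 10.0  # kg/t seeds
    oil_recovery_value_fraction: float = 0.60
    oil_price: float = 900.0  # EUR/t
    cake_price: float = 350.0
    capacity_gain_fraction: float = 0.05
    fixed_cost_reduction: float = 0.8  # EUR/t seeds

    def __post_init__(self) -> None:
        for name in (
            "solvent_price_alt",
            "solvent_price_ref",
            "steam_price",
            "oil_price",
            "cake_price",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"configuration error: {name} must be >= 0")
        for name in ("oil_recovery_value_fraction", "capacity_gain_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"configuration error: {name} must be in [0, 1]")


@dataclass(frozen=True)
class BalanceLine:
    label: str
    value: float  # full precision, EUR/t
    reported: float  # rounded for display
    sign: str  # "cost" | "benefit"


@dataclass
class EconomicBalance:
    """Itemized costs and benefits; totals are sums of the reported lines
    (presentation convention), exact totals kept alongside."""

    lines: list[BalanceLine]

    def _sum(self, sign: str, reported: bool) -> float:
        attr = "reported" if reported else "value"
        return sum(getattr(l, attr) for l in self.lines if l.sign == sign)

    @property
    def total_costs(self) -> float:
        return round_half_up(self._sum("cost", reported=True), 1)

    @property
    def total_benefits(self) -> float:
        return round_half_up(self._sum("benefit", reported=True), 1)

    @property
    def net(self) -> float:
        return round_half_up(self.total_benefits - self.total_costs, 1)

    @property
    def exact_total_costs(self) -> float:
        return self._sum("cost", reported=False)

    @property
    def exact_total_benefits(self) -> float:
        return self._sum("benefit", reported=False)

    @property
    def exact_net(self) -> float:
        return self.exact_total_benefits - self.exact_total_costs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"label": l.label, "eur_per_t": l.value, "reported": l.reported, "sign": l.sign}
                for l in self.lines
            ]
        )

    def render_text(self) -> str:
        lines = ["Economic balance (EUR per tonne of seeds)", "-" * 44]
        for sign in ("cost", "benefit"):
            for l in self.lines:
                if l.sign == sign:
                    lines.append(f"  {l.label:32s} {l.reported:6.1f}  ({sign})")
        lines.append(f"  {'total costs':32s} {self.total_costs:6.1f}")
        lines.append(f"  {'total benefits':32s} {self.total_benefits:6.1f}")
        lines.append(f"  {'net (benefits - costs)':32s} {self.net:6.1f}")
        return "\n".join(lines)


def solvent_makeup_cost(a: EconomicAssumptions) -> float:
    """Make-up cost of switching solvent: consumption × Δprice (EUR/t)."""
    if not (a.solvent_consumption > 0):
        raise ValueError("solvent_consumption must be > 0")
    return a.solvent_consumption * (a.solvent_price_alt - a.solvent_price_ref)


def steam_cost(extra_steam: float, steam_price: float) -> float:
    """Cost of extra steam (kg/t × EUR/t / 1000)."""
    return extra_steam * steam_price / 1000.0


def oil_shift_benefit(a: EconomicAssumptions, net_oil_kg_per_t: float) -> float:
    """Value of shifting product mass from cake to oil.

    The extra oil displaces an equal mass of cake, so the benefit is
    net_oil × (oil price − cake price) / 1000 EUR per tonne of seeds.
    """
    if net_oil_kg_per_t < 0:
        raise ValueError("net oil shift must be >= 0")
    return net_oil_kg_per_t * (a.oil_price - a.cake_price) / 1000.0


def balance(a: EconomicAssumptions) -> EconomicBalance:
    """Full substitution balance from one set of assumptions.

    The oil benefit is taken on the recoverable-value share of the gross
    extra oil (``extra_oil_gross × oil_recovery_value_fraction``).
    """
    makeup = solvent_makeup_cost(a)
    steam = steam_cost(a.extra_steam, a.steam_price)
    net_oil = a.extra_oil_gross * a.oil_recovery_value_fraction
    oil = oil_shift_benefit(a, net_oil)
    fixed = a.fixed_cost_reduction
    lines = [
        # make-up is quoted to the unit in practice; the others to one decimal
        BalanceLine("solvent make-up", makeup, round_half_up(makeup, 0), "cost"),
        BalanceLine("extra steam", steam, round_half_up(steam, 1), "cost"),
        BalanceLine("oil/cake mass shift", oil, round_half_up(oil, 1), "benefit"),
        BalanceLine("fixed-cost reduction", fixed, round_half_up(fixed, 1), "benefit"),
    ]
    return EconomicBalance(lines=lines)
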