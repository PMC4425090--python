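"""Energy and steam ledger of the oilseed crushing process.

Builds a per-step heat/steam accounting for one solvent scenario
(preparation, desolventization, distillation, desolventizer heat recovery,
losses) and compares scenarios.  Heats are in MJ per tonne of crushed seeds,
steam in kg per tonne; the preparation steps carry no solvent dependence and
enter as fixed entries.

Steam conversion: desolventization rows use 10-bar saturated steam (latent
heat), distillation and preparation rows 6-bar, sparged steam is live steam
accounted at its total enthalpy.  Rounding for display is half-up at the
precision of each cell; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsp import SolventRecord

__all__ = [
    "SteamProperties",
    "PrepStep",
    "ProcessScenario",
    "LedgerRow",
    "EnergyLedger",
    "ScenarioComparison",
    "sensible_heat",
    "vaporization_heat",
    "sparged_steam",
    "heat_recovery",
    "steam_from_heat",
    "build_ledger",
    "compare_scenarios",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (ledger display convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class SteamProperties:
    """Steam classes used by the ledger (kJ/kg; price EUR/t).

    Latent heats are for 6-bar and 10-bar saturated steam; sparged steam is
    injected live, so its full enthalpy is charged.
    """

    latent_heat_6bar: float = 2085.0
    latent_heat_10bar: float = 2000.0
    total_enthalpy_sparged: float = 2778.0
    price_eur_t: float = 30.0

    def __post_init__(self) -> None:
        if not (
            self.total_enthalpy_sparged
            > max(self.latent_heat_6bar, self.latent_heat_10bar)
            and min(self.latent_heat_6bar, self.latent_heat_10bar) > 0
        ):
            raise ValueError("need total_enthalpy_sparged > latent heats > 0")

    def latent_heat(self, steam_class: str) -> float:
        try:
            return {"6bar": self.latent_heat_6bar, "10bar": self.latent_heat_10bar}[
                steam_class
            ]
        except KeyError:
            raise ValueError(f"unknown steam class {steam_class!r}") from None


@dataclass(frozen=True)
class PrepStep:
    """A fixed preparation heat entry (solvent independent)."""

    step: str
    material: str
    change: str
    heat_mj_t: float


DEFAULT_PREP_STEPS: tuple[PrepStep, ...] = (
    PrepStep("Conditioning", "Seeds", "T: 15 -> 60 C", 78.0),
    PrepStep("Cooking", "Flakes", "T: 55 -> 105 C", 110.0),
    PrepStep("Cooking", "Flakes", "Vaporization of ~30 kg of water", 66.0),
    PrepStep("Cooking", "Air (dry)", "T: 20 -> 100 C for drying", 15.0),
)


@dataclass
class ProcessScenario:
    """One solvent scenario of the crushing process (basis: 1 t of seeds).

    ``retained_solvent`` is the solvent held by the dry matter entering the
    desolventizer, in kg/t (``retained_mode="mass"``) or L/t
    (``retained_mode="volume"``, converted with the solvent density).
    ``miscella_heating_heat`` is carried as a constant because the printed
    source balance for that step cannot be reproduced from any consistent
    mass/cp combination.
    """

    solvent: SolventRecord
    sparged_steam_ratio: float  # kg steam per kg solvent stripped
    retained_solvent: float
    oil_to_distillation: float  # kg oil passing the miscella distillation
    miscella_heating_heat: float  # MJ/t, fixed entry
    retained_mode: str = "mass"
    prep_steps: tuple[PrepStep, ...] = DEFAULT_PREP_STEPS
    meal_mass: float = 550.0  # kg/t
    meal_cp: float = 1.9  # kJ/(°C kg)
    oil_cp: float = 2.0
    extraction_t: float = 55.0  # °C
    desolventizer_exit_t: float = 105.0
    oil_final_t: float = 110.0
    miscella_oil_fraction: float = 0.25
    condensed_steam_heat: float = 38.0  # MJ/t
    heat_recovery_fraction: float = 0.75
    loss_fraction: float = 0.05

    def __post_init__(self) -> None:
        required = ("cp", "t_boil", "dh_vap")
        for name in required:
            if getattr(self.solvent, name) is None:
                raise ValueError(
                    f"scenario configuration error: solvent.{name} is required"
                )
        for name in ("heat_recovery_fraction", "loss_fraction", "miscella_oil_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"scenario configuration error: {name} must be in [0, 1]")
        for name in ("meal_mass", "retained_solvent", "oil_to_distillation", "sparged_steam_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"scenario configuration error: {name} must be >= 0")
        if self.retained_mode not in ("mass", "volume"):
            raise ValueError("scenario configuration error: retained_mode must be 'mass' or 'volume'")
        if self.retained_mode == "volume" and self.solvent.density is None:
            raise ValueError(
                "scenario configuration error: volumetric retention requires solvent.density"
            )

    @property
    def retained_solvent_kg(self) -> float:
        if self.retained_mode == "mass":
            return self.retained_solvent
        # L/t with density in g/cm3 == kg/L
        return self.retained_solvent * self.solvent.density


@dataclass(frozen=True)
class LedgerRow:
    step: str
    material: str
    change: str
    heat_mj_t: float
    steam_kg_t: float
    category: str  # preparation | desolventization | distillation | recovery | losses


CATEGORIES = ("preparation", "desolventization", "distillation", "recovery", "losses")


@dataclass
class EnergyLedger:
    """Ordered heat/steam entries for one scenario, with subtotals."""

    scenario_name: str
    rows: list[LedgerRow]

    def subtotal(self, category: str) -> tuple[float, float]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        heat = sum(r.heat_mj_t for r in self.rows if r.category == category)
        steam = sum(r.steam_kg_t for r in self.rows if r.category == category)
        return heat, steam

    @property
    def preparation_heat(self) -> float:
        return self.subtotal("preparation")[0]

    @property
    def distillation_heat(self) -> float:
        return self.subtotal("distillation")[0]

    @property
    def extraction_heat(self) -> float:
        """Extraction-stage heat: desolventization + distillation + recovery."""
        return sum(self.subtotal(c)[0] for c in ("desolventization", "distillation", "recovery"))

    @property
    def extraction_steam(self) -> float:
        return sum(self.subtotal(c)[1] for c in ("desolventization", "distillation", "recovery"))

    @property
    def total_heat(self) -> float:
        """Preparation + extraction + losses, MJ/t."""
        return sum(r.heat_mj_t for r in self.rows)

    @property
    def total_steam(self) -> float:
        return sum(r.steam_kg_t for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    "material": r.material,
                    "change": r.change,
                    "heat_MJ_per_t": r.heat_mj_t,
                    "steam_kg_per_t": r.steam_kg_t,
                    "category": r.category,
                }
                for r in self.rows
            ]
        )

    def render_text(self) -> str:
        lines = [f"Energy ledger - {self.scenario_name}", "=" * 58]
        lines.append(f"{'step / material / change':38s} {'MJ/t':>8s} {'kg/t':>8s}")
        for cat in CATEGORIES:
            cat_rows = [r for r in self.rows if r.category == cat]
            if not cat_rows:
                continue
            for r in cat_rows:
                label = f"{r.step} | {r.material} | {r.change}"
                lines.append(
                    f"{label[:38]:38s} {round_half_up(r.heat_mj_t, 1):8.1f} "
                    f"{round_half_up(r.steam_kg_t, 1):8.1f}"
                )
            h, s = self.subtotal(cat)
            lines.append(
                f"{'  subtotal ' + cat:38s} {round_half_up(h, 1):8.1f} {round_half_up(s, 1):8.1f}"
            )
        lines.append("-" * 58)
        lines.append(
            f"{'TOTAL (preparation + extraction + losses)':38s} "
            f"{round_half_up(self.total_heat):8.0f} {round_half_up(self.total_steam):8.0f}"
        )
        return "\n".join(lines)


def sensible_heat(mass: float, cp: float, t_from: float, t_to: float) -> float:
    """Sensible heat mass·cp·ΔT in MJ/t (mass kg/t, cp kJ/(°C kg))."""
    if t_to < t_from:
        raise ValueError(f"negative temperature change: {t_from} -> {t_to}")
    return mass * cp * (t_to - t_from) / 1000.0


def vaporization_heat(mass: float, dh_vap: float) -> float:
    """Latent heat mass·Δh_vap in MJ/t (mass kg/t, Δh_vap kJ/kg)."""
    if mass < 0 or dh_vap < 0:
        raise ValueError("mass and dh_vap must be >= 0")
    return mass * dh_vap / 1000.0


def sparged_steam(
    solvent_mass: float, ratio: float, steam: SteamProperties
) -> tuple[float, float]:
    """Live-steam demand for stripping: (steam kg/t, heat MJ/t)."""
    if ratio < 0:
        raise ValueError("sparged steam ratio must be >= 0")
    kg = solvent_mass * ratio
    return kg, kg * steam.total_enthalpy_sparged / 1000.0


def heat_recovery(distillation_total: float, fraction: float = 0.75) -> float:
    """Desolventizer-gas heat credit: −fraction · distillation heat (MJ/t)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("recovery fraction must be in [0, 1]")
    return -fraction * distillation_total


def steam_from_heat(heat: float, steam_class: str, steam: SteamProperties) -> float:
    """Convert an indirect-heat requirement (MJ/t) to steam mass (kg/t) at
    the latent heat of the given class ('6bar' or '10bar')."""
    if heat < 0:
        raise ValueError("heat must be >= 0")
    return heat * 1000.0 / steam.latent_heat(steam_class)


def build_ledger(
    sc: ProcessScenario, steam: SteamProperties | None = None
) -> EnergyLedger:
    """Assemble the full heat/steam ledger for one scenario.

    Rows: fixed preparation entries; desolventization (meal sensible heat,
    retained-solvent sensible heat to the boiling point, retained-solvent
    vaporization, sparged steam, condensed-steam allowance); distillation
    (miscella heating constant, oil sensible heat from the boiling point to
    the final temperature, vaporization of the miscella solvent at the
    configured oil fraction); the desolventizer heat-recovery credit; and a
    loss charge on preparation + extraction.
    """
    if steam is None:
        steam = SteamProperties()
    solv = sc.solvent
    rows: list[LedgerRow] = []

    for p in sc.prep_steps:
        rows.append(
            LedgerRow(
                p.step,
                p.material,
                p.change,
                p.heat_mj_t,
                steam_from_heat(p.heat_mj_t, "6bar", steam),
                "preparation",
            )
        )

    # --- desolventization (10-bar steam) ---
    meal_heat = sensible_heat(sc.meal_mass, sc.meal_cp, sc.extraction_t, sc.desolventizer_exit_t)
    rows.append(
        LedgerRow(
            "Desolventization",
            "Meal",
            f"T: {sc.extraction_t:g} -> {sc.desolventizer_exit_t:g} C",
            meal_heat,
            steam_from_heat(meal_heat, "10bar", steam),
            "desolventization",
        )
    )
    retained = sc.retained_solvent_kg
    solv_sens = sensible_heat(retained, solv.cp, sc.extraction_t, solv.t_boil)
    rows.append(
        LedgerRow(
            "Desolventization",
            "Solvent",
            f"T: {sc.extraction_t:g} -> Bp",
            solv_sens,
            steam_from_heat(solv_sens, "10bar", steam),
            "desolventization",
        )
    )
    solv_vap = vaporization_heat(retained, solv.dh_vap)
    rows.append(
        LedgerRow(
            "Desolventization",
            "Solvent",
            "Vaporization",
            solv_vap,
            steam_from_heat(solv_vap, "10bar", steam),
            "desolventization",
        )
    )
    sparged_kg, sparged_heat = sparged_steam(retained, sc.sparged_steam_ratio, steam)
    rows.append(
        LedgerRow(
            "Desolventization", "Steam", "Sparged", sparged_heat, sparged_kg, "desolventization"
        )
    )
    rows.append(
        LedgerRow(
            "Desolventization",
            "Steam",
            "Condensed",
            sc.condensed_steam_heat,
            sc.condensed_steam_heat * 1000.0 / steam.total_enthalpy_sparged,
            "desolventization",
        )
    )

    # --- distillation (6-bar steam) ---
    rows.append(
        LedgerRow(
            "Distillation",
            "Miscella",
            f"T: {sc.extraction_t:g} -> Bp",
            sc.miscella_heating_heat,
            steam_from_heat(sc.miscella_heating_heat, "6bar", steam),
            "distillation",
        )
    )
    oil_heat = sensible_heat(sc.oil_to_distillation, sc.oil_cp, solv.t_boil, sc.oil_final_t)
    rows.append(
        LedgerRow(
            "Distillation",
            "Oil",
            f"T: Bp -> {sc.oil_final_t:g} C",
            oil_heat,
            steam_from_heat(oil_heat, "6bar", steam),
            "distillation",
        )
    )
    if not (0.0 < sc.miscella_oil_fraction < 1.0) and sc.oil_to_distillation > 0:
        raise ValueError(
            "scenario configuration error: miscella_oil_fraction must be in (0, 1) "
            "when oil is distilled"
        )
    miscella_solvent = (
        sc.oil_to_distillation * (1.0 - sc.miscella_oil_fraction) / sc.miscella_oil_fraction
        if sc.oil_to_distillation > 0
        else 0.0
    )
    misc_vap = vaporization_heat(miscella_solvent, solv.dh_vap)
    rows.append(
        LedgerRow(
            "Distillation",
            "Solvent",
            "Vaporization",
            misc_vap,
            steam_from_heat(misc_vap, "6bar", steam),
            "distillation",
        )
    )

    # --- desolventizer-gas recovery credit ---
    dist_total = sc.miscella_heating_heat + oil_heat + misc_vap
    credit = heat_recovery(dist_total, sc.heat_recovery_fraction)
    rows.append(
        LedgerRow(
            "Recovery",
            "Gas from the DT",
            "Heat recovered",
            credit,
            credit * 1000.0 / steam.latent_heat_6bar,
            "recovery",
        )
    )

    # --- losses on preparation + extraction ---
    heat_so_far = sum(r.heat_mj_t for r in rows)
    steam_so_far = sum(r.steam_kg_t for r in rows)
    rows.append(
        LedgerRow(
            "Losses",
            "-",
            f"{100 * sc.loss_fraction:g}% of preparation + extraction",
            sc.loss_fraction * heat_so_far,
            sc.loss_fraction * steam_so_far,
            "losses",
        )
    )

    return EnergyLedger(scenario_name=solv.name, rows=rows)


@dataclass
class ScenarioComparison:
    """Row-wise and total deltas between two scenario ledgers (b minus a)."""

    rows: pd.DataFrame
    heat_delta_mj_t: float
    steam_delta_kg_t: float
    heat_increase_pct: int
    steam_increase_pct: int

    def render_text(self, name_a: str, name_b: str) -> str:
        return (
            f"Scenario comparison: {name_b} vs {name_a}\n"
            f"  heat:  {self.heat_delta_mj_t:+.1f} MJ/t ({self.heat_increase_pct:+d}%)\n"
            f"  steam: {self.steam_delta_kg_t:+.1f} kg/t ({self.steam_increase_pct:+d}%)"
        )


def compare_scenarios(a: EnergyLedger, b: EnergyLedger) -> ScenarioComparison:
    """Per-row and total differences between two ledgers with identical
    row structure; percentages are on the grand totals, rounded half-up to
    the nearest integer percent."""
    keys_a = [(r.step, r.material, r.change.split(":")[0], r.category) for r in a.rows]
    keys_b = [(r.step, r.material, r.change.split(":")[0], r.category) for r in b.rows]
    if keys_a != keys_b:
        unmatched = [k for k in keys_a if k not in keys_b] + [
            k for k in keys_b if k not in keys_a
        ]
        raise ValueError(f"ledger row structures differ; unmatched rows: {unmatched}")

    rows = pd.DataFrame(
        {
            "step": [r.step for r in a.rows],
            "material": [r.material for r in a.rows],
            "category": [r.category for r in a.rows],
            "heat_a": [r.heat_mj_t for r in a.rows],
            "heat_b": [r.heat_mj_t for r in b.rows],
            "steam_a": [r.steam_kg_t for r in a.rows],
            "steam_b": [r.steam_kg_t for r in b.rows],
        }
    )
    rows["heat_delta"] = rows["heat_b"] - rows["heat_a"]
    rows["steam_delta"] = rows["steam_b"] - rows["steam_a"]

    heat_delta = b.total_heat - a.total_heat
    steam_delta = b.total_steam - a.total_steam
    heat_pct = int(round_half_up(100.0 * heat_delta / a.total_heat)) if a.total_heat else 0
    steam_pct = int(round_half_up(100.0 * steam_delta / a.total_steam)) if a.total_steam else 0
    return ScenarioComparison(
        rows=rows,
        heat_delta_mj_t=heat_delta,
        steam_delta_kg_t=steam_delta,
        heat_increase_pct=heat_pct,
        steam_increase_pct=steam_pct,
    )
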