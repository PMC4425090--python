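"""End-to-end solvent-substitution report.

Chains the pipeline stages — solubility screening, extraction kinetics,
washing simulation, energy ledger, economics and lipid composition — on the
packaged fixtures and synthetic data, and writes per-stage CSVs plus one
combined markdown report.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import datasets, economics, energy, hsp, kinetics, synthetic
from .composition import class_sums, compare_profiles, vitamin_e_equivalents

log = logging.getLogger("greenextract")

STAGES = ("hsp", "kinetics", "washes", "energy", "economics", "composition")


@dataclass
class RunConfig:
    """Paths and knobs of one full report run.

    ``None`` paths fall back to the packaged fixtures; any path supplied must
    exist at validation time.
    """

    out_dir: Path
    seed: int = 0
    solvents_path: Path | None = None
    sphere_fit_solvents_path: Path | None = None
    red_panel_path: Path | None = None
    scenario_ref_path: Path | None = None
    scenario_alt_path: Path | None = None
    economics_path: Path | None = None
    washes_path: Path | None = None
    kinetics_path: Path | None = None
    verbosity: int = 0

    def validate(self) -> None:
        for name in (
            "solvents_path",
            "sphere_fit_solvents_path",
            "red_panel_path",
            "scenario_ref_path",
            "scenario_alt_path",
            "economics_path",
            "washes_path",
            "kinetics_path",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config error: {name} -> {path} does not exist")


def run_full_report(cfg: RunConfig) -> dict[str, object]:
    """Execute all stages; returns per-stage results and writes the bundle.

    Raises on the first failing stage after logging its name; partial
    outputs written so far are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    summary: list[str] = ["# Solvent substitution report", ""]

    stage = "hsp"
    try:
        solvents = datasets.load_solvents(cfg.solvents_path or "default")
        fit_set = datasets.load_solvents(cfg.sphere_fit_solvents_path or "sphere_fit")
        panel = datasets.load_red_panel(cfg.red_panel_path)
        fits = hsp.fit_red_panel(panel, {n: s.hansen for n, s in fit_set.items()})
        spheres = [r.sphere for r in fits.values()]
        desirable = [lbl for lbl in fits if lbl.startswith(("TAG", "T", "S"))]
        screen = hsp.screening_report(
            list(solvents.values()),
            spheres,
            desirable=desirable,
            undesirable=["W"],
            reference="n-hexane",
        )
        screen.to_csv(out / "hsp_screening.csv")
        sphere_rows = pd.DataFrame(
            {
                "solute": list(fits),
                "delta_d": [r.sphere.center.delta_d for r in fits.values()],
                "delta_p": [r.sphere.center.delta_p for r in fits.values()],
                "delta_h": [r.sphere.center.delta_h for r in fits.values()],
                "radius_r0": [r.sphere.radius_r0 for r in fits.values()],
                "rms": [r.rms for r in fits.values()],
            }
        )
        sphere_rows.to_csv(out / "hsp_spheres.csv", index=False)
        results["hsp"] = {"fits": fits, "screening": screen}
        methf_red = {lbl: fits[lbl].predicted(
            {"MeTHF": solvents["MeTHF"].hansen})["MeTHF"] for lbl in ("TAG1", "W")}
        summary += [
            "## Solubility screening",
            f"- fitted {len(fits)} solute spheres, worst RMS "
            f"{max(r.rms for r in fits.values()):.3f}",
            f"- MeTHF: RED(TAG1) = {methf_red['TAG1']:.2f} (good), "
            f"RED(wax) = {methf_red['W']:.2f} (avoided)",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    stage = "kinetics"
    try:
        kin_cfg = datasets.load_kinetics_defaults(cfg.kinetics_path)
        fits = {}
        for key in ("hexane", "methf"):
            spec = synthetic.KineticGenSpec(
                deff=float(kin_cfg[key]["deff"]),
                rd=float(kin_cfg["rd"]),
                x_inf=float(kin_cfg[key]["x_inf"]),
                x0=float(kin_cfg["x0"]),
                t0_min=float(kin_cfg["t0_min"]),
                noise_model="none",
                withdrawal_mass_g=1.0,
                seed=cfg.seed,
                solvent_name=key,
            )
            run = synthetic.gen_kinetics(spec)
            fits[key] = kinetics.fit_crank(run.dataset, spec.t0_min)
            datasets.write_kinetics_csv(run.dataset, out / f"kinetics_{key}.csv")
        ratio = fits["methf"].deff_m2_s / fits["hexane"].deff_m2_s
        pd.DataFrame(
            {
                "solvent": list(fits),
                "deff_m2_s": [f.deff_m2_s for f in fits.values()],
                "x0_g_per_gDM": [f.x0 for f in fits.values()],
                "r2": [f.r2 for f in fits.values()],
            }
        ).to_csv(out / "kinetics_fits.csv", index=False)
        results["kinetics"] = {"fits": fits, "deff_ratio": ratio}
        summary += [
            "## Extraction kinetics",
            f"- fitted Deff: hexane {fits['hexane'].deff_m2_s:.3e}, "
            f"MeTHF {fits['methf'].deff_m2_s:.3e} m2/s",
            f"- Deff ratio (MeTHF / hexane): {ratio:.2f} (>= 3.5)",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    stage = "washes"
    try:
        wcfg = datasets.load_washes_config(cfg.washes_path)
        sims = {
            which: kinetics.simulate_washes(
                datasets.washing_scenario_from_config(wcfg, which)
            )
            for which in ("ref", "alt")
        }
        pd.concat(
            {k: s.table for k, s in sims.items()}, names=["scenario"]
        ).to_csv(out / "washes.csv")
        extrap = datasets.load_residual_extrapolation()
        projected, gain = kinetics.extrapolate_residual(
            extrap["industry_residual_kg_per_t"],
            extrap["pilot_residual_ref_pct"],
            extrap["pilot_residual_alt_pct"],
        )
        results["washes"] = {"sims": sims, "projected": projected, "gain": gain}
        summary += [
            "## Washing stages and residual oil",
            f"- washes to 95% recovery: reference {sims['ref'].washes_to_reach(95)}, "
            f"alternative {sims['alt'].washes_to_reach(95)}",
            f"- projected industrial residual {projected:.1f} kg/t, oil gain {gain:.1f} kg/t",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    stage = "energy"
    try:
        sc_ref, steam_ref = datasets.load_scenario(cfg.scenario_ref_path or "hexane")
        sc_alt, steam_alt = datasets.load_scenario(cfg.scenario_alt_path or "methf")
        ledger_ref = energy.build_ledger(sc_ref, steam_ref)
        ledger_alt = energy.build_ledger(sc_alt, steam_alt)
        comparison = energy.compare_scenarios(ledger_ref, ledger_alt)
        ledger_ref.to_frame().to_csv(out / "energy_ref.csv", index=False)
        ledger_alt.to_frame().to_csv(out / "energy_alt.csv", index=False)
        comparison.rows.to_csv(out / "energy_comparison.csv", index=False)
        results["energy"] = {
            "ref": ledger_ref,
            "alt": ledger_alt,
            "comparison": comparison,
        }
        summary += [
            "## Energy ledger",
            f"- heat: {ledger_ref.total_heat:.0f} vs {ledger_alt.total_heat:.0f} MJ/t "
            f"({comparison.heat_delta_mj_t:+.0f})",
            f"- steam: {ledger_ref.total_steam:.0f} vs {ledger_alt.total_steam:.0f} kg/t "
            f"({comparison.steam_increase_pct:+d}%)",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    stage = "economics"
    try:
        assumptions = datasets.load_economics(cfg.economics_path)
        bal = economics.balance(assumptions)
        bal.to_frame().to_csv(out / "economics.csv", index=False)
        results["economics"] = bal
        summary += [
            "## Economics",
            f"- costs {bal.total_costs:.1f} EUR/t vs benefits {bal.total_benefits:.1f} EUR/t "
            f"(net {bal.net:+.1f})",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    stage = "composition"
    try:
        prof_ref = datasets.load_fatty_acid_profile("hexane")
        prof_alt = datasets.load_fatty_acid_profile("methf")
        sums = {name: class_sums(p) for name, p in (("hexane", prof_ref), ("methf", prof_alt))}
        comparison = compare_profiles(prof_ref, prof_alt)
        comparison.to_csv(out / "composition_comparison.csv", index=False)
        vite = {
            name: vitamin_e_equivalents(datasets.load_tocopherols(name))
            for name in ("hexane", "methf")
        }
        results["composition"] = {"class_sums": sums, "comparison": comparison, "vitamin_e": vite}
        summary += [
            "## Lipid composition",
            f"- MeTHF class sums: SFA {sums['methf']['SFA']:.2f}, "
            f"MUFA {sums['methf']['MUFA']:.2f}, PUFA {sums['methf']['PUFA']:.2f} %",
            f"- vitamin E: {vite['hexane'].te_per_100g:.1f} vs "
            f"{vite['methf'].te_per_100g:.1f} TE/100 g",
            f"- significant fatty-acid differences: {comparison.attrs['n_significant']}",
            "",
        ]
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    (out / "report.md").write_text("\n".join(summary))
    return results
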