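"""Synthetic data generators emulating the bench experiments.

Every generator is a pure function of its specification and seed, so test
suites and reports can run fully offline and deterministically:

* :func:`gen_kinetics` forward-simulates a maceration-with-sampling
  experiment: the diffusion model drives the true yield curve, about 1 mL of
  miscella is withdrawn at each grid time, the extract fraction of each
  sample is measured (optionally with noise), and the withdrawal bookkeeping
  is logged so the inverse correction can be exercised.
* :func:`gen_composition` draws replicate analyte tables around configured
  means/sds (truncated at zero, renormalized above 100%).
* :func:`gen_red_panel` evaluates a known solubility sphere over a solvent
  set, with configurable rounding and jitter, for sphere-inversion tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hsp import HansenParameters, RedObservation, SoluteSphere, red
from .kinetics import (
    DEFAULT_T0_MIN,
    KineticDataset,
    correct_for_sampling,
    crank_profile,
)

__all__ = [
    "DEFAULT_SAMPLING_GRID_MIN",
    "KineticGenSpec",
    "KineticRun",
    "CompositionGenSpec",
    "gen_kinetics",
    "gen_composition",
    "gen_red_panel",
]

#: Sampling grid (minutes): dense early draws, then every 30 min to 2 h.
DEFAULT_SAMPLING_GRID_MIN: tuple[float, ...] = (1, 3, 5, 10, 15, 20, 30, 60, 90, 120)

NOISE_MODELS = ("none", "additive", "multiplicative")


@dataclass
class KineticGenSpec:
    """Specification of one synthetic kinetic run.

    ``noise_level`` is an absolute sigma (g/g DM) for additive noise and a
    coefficient of variation for multiplicative noise.  ``withdrawal_mass_g``
    is the liquid mass drawn per sample; set to 0 to disable sampling
    perturbation.  Defaults mirror a 30 g batch macerated in 150 mL of
    solvent.
    """

    deff: float
    rd: float
    x_inf: float
    x0: float
    t0_min: float = DEFAULT_T0_MIN
    noise_model: str = "none"
    noise_level: float = 0.02
    sampling_grid_min: tuple[float, ...] = DEFAULT_SAMPLING_GRID_MIN
    seed: int | None = None
    withdrawal_mass_g: float = 1.0
    solvent_mass_g: float = 120.0
    dry_matter_g: float = 30.0
    solvent_name: str | None = None
    temperature_c: float | None = 55.0
    n_terms: int = 400

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_model != "none" and self.seed is None:
            raise ValueError("seed is mandatory when noise is enabled")
        for name in ("deff", "rd", "x_inf", "solvent_mass_g", "dry_matter_g"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.x0 < self.x_inf):
            raise ValueError("need 0 <= x0 < x_inf")
        if self.withdrawal_mass_g < 0:
            raise ValueError("withdrawal_mass_g must be >= 0")
        grid = tuple(float(t) for t in self.sampling_grid_min)
        if any(t < 0 for t in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("sampling grid must be non-negative and strictly increasing")
        self.sampling_grid_min = grid


@dataclass
class KineticRun:
    """Output bundle of :func:`gen_kinetics`."""

    dataset: KineticDataset
    withdrawals: pd.DataFrame
    x_true: np.ndarray
    pre_t0_mask: np.ndarray  # points in the convective stage (t <= t0)


def _true_profile(spec: KineticGenSpec) -> np.ndarray:
    """Model yield over the grid; before t0 the convective washing stage is
    represented as a linear ramp from 0 to x0 (the diffusion series is only
    defined past t0)."""
    t = np.asarray(spec.sampling_grid_min, dtype=float)
    x = np.empty_like(t)
    pre = t <= spec.t0_min
    x[pre] = spec.x0 * t[pre] / spec.t0_min
    if np.any(~pre):
        x[~pre] = crank_profile(
            spec.deff, spec.rd, spec.x_inf, spec.x0, spec.t0_min, t[~pre], spec.n_terms
        )
    return x


def gen_kinetics(spec: KineticGenSpec) -> KineticRun:
    """Simulate a kinetic experiment with per-draw mass bookkeeping.

    The withdrawal log tracks, for every draw, the true extract fraction in
    the flask, the measured (noisy) fraction, and the extract/solvent masses
    removed, keeping an exact running mass balance.  The returned dataset is
    the sampling-corrected yield series reconstructed from the *measured*
    fractions, i.e. what an experimenter would tabulate.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_grid_min, dtype=float)
    x_true = _true_profile(spec)

    solvent_removed = 0.0
    extract_removed = 0.0
    log_rows = []
    measured_fractions = np.empty_like(x_true)
    for j, (tj, xj) in enumerate(zip(t, x_true)):
        extracted_mass = xj * spec.dry_matter_g
        e_flask = extracted_mass - extract_removed
        s_flask = spec.solvent_mass_g - solvent_removed
        if s_flask <= 0 or e_flask < 0:
            raise ValueError("withdrawals exhausted the batch during simulation")
        f_true = e_flask / (e_flask + s_flask)
        f_meas = f_true
        if spec.noise_model == "additive":
            f_meas = f_true + rng.normal(0.0, spec.noise_level)
        elif spec.noise_model == "multiplicative":
            f_meas = f_true * (1.0 + rng.normal(0.0, spec.noise_level))
        f_meas = float(np.clip(f_meas, 0.0, 0.999))
        draw = spec.withdrawal_mass_g
        log_rows.append(
            {
                "time_min": tj,
                "mass_drawn_g": draw,
                "extract_fraction_true": f_true,
                "extract_fraction_measured": f_meas,
                "extract_removed_g": draw * f_true,
                "solvent_removed_g": draw * (1.0 - f_true),
                "extract_in_flask_g": e_flask,
                "solvent_in_flask_g": s_flask,
                "extracted_mass_true_g": extracted_mass,
            }
        )
        measured_fractions[j] = f_meas
        extract_removed += draw * f_true
        solvent_removed += draw * (1.0 - f_true)

    withdrawals = pd.DataFrame(log_rows)
    dataset = correct_for_sampling(
        t,
        withdrawals["mass_drawn_g"].to_numpy(),
        measured_fractions,
        spec.solvent_mass_g,
        spec.dry_matter_g,
        rd_m=spec.rd,
        temperature_c=spec.temperature_c,
        solvent_name=spec.solvent_name,
        x_inf_hint=spec.x_inf,
    )
    return KineticRun(
        dataset=dataset,
        withdrawals=withdrawals,
        x_true=x_true,
        pre_t0_mask=t <= spec.t0_min,
    )


@dataclass
class CompositionGenSpec:
    """Replicate-table generator spec: analyte -> (mean, sd), n replicates."""

    analytes: Mapping[str, tuple[float, float]]
    n_replicates: int = 3
    seed: int | None = None
    unit: str = "%"
    renormalize_above: float | None = 100.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name, (mean, sd) in self.analytes.items():
            if mean < 0:
                raise ValueError(f"negative mean for analyte {name!r}")
            if sd < 0:
                raise ValueError(f"negative sd for analyte {name!r}")


def gen_composition(spec: CompositionGenSpec) -> pd.DataFrame:
    """Draw replicate composition tables (analytes × replicates).

    Gaussian draws truncated at zero; any replicate whose column sum exceeds
    ``renormalize_above`` is rescaled onto that total.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.analytes)
    means = np.array([spec.analytes[n][0] for n in names])
    sds = np.array([spec.analytes[n][1] for n in names])
    draws = rng.normal(
        means[:, None], sds[:, None], size=(len(names), spec.n_replicates)
    )
    draws = np.clip(draws, 0.0, None)
    if spec.renormalize_above is not None:
        totals = draws.sum(axis=0)
        over = totals > spec.renormalize_above
        draws[:, over] *= spec.renormalize_above / totals[over]
    return pd.DataFrame(
        draws,
        index=pd.Index(names, name="analyte"),
        columns=[f"rep{i + 1}" for i in range(spec.n_replicates)],
    )


def gen_red_panel(
    sphere: SoluteSphere,
    solvents: Mapping[str, HansenParameters],
    rounding_decimals: int | None = 2,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> list[RedObservation]:
    """Evaluate a known sphere over a solvent set into a RED panel.

    REDs are computed exactly, optionally jittered (Gaussian, requires a
    seed) and rounded to ``rounding_decimals`` (None disables rounding).
    """
    if len(solvents) < 4:
        raise ValueError("a useful RED panel needs >= 4 solvents")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if jitter_sd > 0 and seed is None:
        raise ValueError("seed is mandatory when jitter is enabled")
    rng = np.random.default_rng(seed)
    panel = []
    for name, hansen in solvents.items():
        value = red(hansen, sphere)
        if jitter_sd > 0:
            value = max(value + rng.normal(0.0, jitter_sd), 0.0)
        if rounding_decimals is not None:
            value = round(value, rounding_decimals)
        panel.append(
            RedObservation(solvent_name=name, solute_label=sphere.label, red=value)
        )
    return panel
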