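"""Hansen solubility parameter (HSP) arithmetic and solvent screening.

A solute is represented by a *solubility sphere* in Hansen space: a centre
``(delta_d, delta_p, delta_h)`` plus an interaction radius ``R0``.  A solvent
dissolves the solute when its relative energy difference

    RED = Ra(solvent, centre) / R0

is below one, where ``Ra`` is the conventional Hansen distance with a factor-4
weight on the dispersion axis.  Solute spheres are never estimated by group
contribution here; they are either supplied by the user or recovered by
inverting a panel of observed RED values (:func:`fit_solute_sphere`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CAL_TO_MPA_SQRT",
    "HansenParameters",
    "SoluteSphere",
    "SolventRecord",
    "RedObservation",
    "SphereFitError",
    "SphereFitResult",
    "total_parameter",
    "hansen_distance",
    "red",
    "classify_red",
    "fit_solute_sphere",
    "fit_red_panel",
    "evaporation_energy",
    "screening_report",
]

#: Conversion factor from cal^0.5 cm^-3/2 to MPa^0.5.
CAL_TO_MPA_SQRT = 2.0455

#: Default seed for the randomized multi-start of the sphere fit.
FIT_SEED = 1729


@dataclass(frozen=True)
class HansenParameters:
    """A point in Hansen space, all components in MPa^0.5."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_d, self.delta_p, self.delta_h], dtype=float)

    @classmethod
    def from_cal(cls, delta_d: float, delta_p: float, delta_h: float) -> "HansenParameters":
        """Build from values given in cal^0.5 cm^-3/2."""
        return cls(
            delta_d * CAL_TO_MPA_SQRT,
            delta_p * CAL_TO_MPA_SQRT,
            delta_h * CAL_TO_MPA_SQRT,
        )


@dataclass(frozen=True)
class SoluteSphere:
    """Solubility sphere of one solute: centre plus interaction radius R0."""

    center: HansenParameters
    radius_r0: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius_r0 > 0):
            raise ValueError(f"radius_r0 must be > 0, got {self.radius_r0!r}")


@dataclass
class SolventRecord:
    """Physical properties of a candidate solvent.

    Only ``name`` and ``hansen`` are mandatory; missing properties are kept as
    ``None`` and reported as absent by :func:`screening_report`.
    Units: cp kJ/(°C kg), t_boil/t_melt °C, dh_vap kJ/kg, density g/cm³,
    viscosity cP, price EUR/kg.
    """

    name: str
    hansen: HansenParameters
    cp: float | None = None
    t_boil: float | None = None
    dh_vap: float | None = None
    density: float | None = None
    t_melt: float | None = None
    viscosity: float | None = None
    price: float | None = None

    def __post_init__(self) -> None:
        if self.dh_vap is not None and not (self.dh_vap > 0):
            raise ValueError(f"dh_vap must be > 0, got {self.dh_vap!r}")
        if (
            self.t_boil is not None
            and self.t_melt is not None
            and not (self.t_boil > self.t_melt)
        ):
            raise ValueError(
                f"t_boil ({self.t_boil}) must exceed t_melt ({self.t_melt})"
            )


@dataclass(frozen=True)
class RedObservation:
    """One observed relative energy difference for a (solvent, solute) pair."""

    solvent_name: str
    solute_label: str
    red: float

    def __post_init__(self) -> None:
        if self.red < 0:
            raise ValueError(f"red must be >= 0, got {self.red!r}")


class SphereFitError(ValueError):
    """Raised when a solubility-sphere fit is degenerate or impossible."""


@dataclass
class SphereFitResult:
    """Outcome of a sphere inversion.

    ``residuals`` maps solvent name to (predicted RED - observed RED);
    ``rms`` is the root-mean-square of those residuals.
    """

    sphere: SoluteSphere
    residuals: dict[str, float]
    rms: float
    converged: bool
    message: str = ""

    def predicted(self, solvents: Mapping[str, HansenParameters]) -> dict[str, float]:
        return {name: red(p, self.sphere) for name, p in solvents.items()}


def total_parameter(p: HansenParameters) -> float:
    """Total solubility parameter: sqrt(delta_d² + delta_p² + delta_h²)."""
    return math.sqrt(p.delta_d**2 + p.delta_p**2 + p.delta_h**2)


def hansen_distance(a: HansenParameters, b: HansenParameters) -> float:
    """Hansen distance Ra = sqrt(4·Δδd² + Δδp² + Δδh²) in MPa^0.5.

    The factor 4 on the dispersion axis makes Ra a metric on the rescaled
    space (2δd, δp, δh).
    """
    return math.sqrt(
        4.0 * (a.delta_d - b.delta_d) ** 2
        + (a.delta_p - b.delta_p) ** 2
        + (a.delta_h - b.delta_h) ** 2
    )


def red(solvent: HansenParameters, sphere: SoluteSphere) -> float:
    """Relative energy difference RED = Ra / R0 (dimensionless)."""
    if not (sphere.radius_r0 > 0):
        raise SphereFitError(f"invalid sphere: radius_r0={sphere.radius_r0!r}")
    return hansen_distance(solvent, sphere.center) / sphere.radius_r0


def classify_red(value: float, tol: float = 1e-9) -> str:
    """Classify a RED value: 'good' (<1), 'poor' (>1), 'borderline' (==1)."""
    if abs(value - 1.0) <= tol:
        return "borderline"
    return "good" if value < 1.0 else "poor"


def _scaled_coords(points: np.ndarray) -> np.ndarray:
    # (2δd, δp, δh): the space in which Ra is Euclidean.
    out = points.copy()
    out[:, 0] *= 2.0
    return out


def fit_solute_sphere(
    observations: Sequence[RedObservation],
    solvents: Mapping[str, HansenParameters],
    *,
    n_random_starts: int = 8,
    seed: int = FIT_SEED,
) -> SphereFitResult:
    """Invert a RED panel into a solute sphere.

    Minimizes sum_i (Ra_i/R0 - red_i)² over the centre and radius by
    multi-start trust-region least squares; starts are placed at the
    observation-weighted solvent centroid, at each solvent, and at seeded
    random perturbations of the centroid.

    Raises :class:`SphereFitError` when fewer than four distinct solvents are
    observed or when their Hansen coordinates are rank-deficient (colinear or
    coplanar), which leaves the sphere centre underdetermined.
    """
    names: list[str] = []
    reds: list[float] = []
    for obs in observations:
        if obs.solvent_name not in solvents:
            raise KeyError(f"no Hansen parameters for solvent {obs.solvent_name!r}")
        if obs.solvent_name in names:
            raise SphereFitError(f"duplicate observation for {obs.solvent_name!r}")
        names.append(obs.solvent_name)
        reds.append(obs.red)

    if len(names) < 4:
        raise SphereFitError(
            f"sphere fit needs >= 4 distinct solvents, got {len(names)}"
        )

    pts = np.array([solvents[n].as_array() for n in names])
    r_obs = np.array(reds, dtype=float)

    scaled = _scaled_coords(pts)
    centred = scaled - scaled.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(scaled).max())) < 3:
        raise SphereFitError(
            "degenerate solvent geometry: Hansen coordinates are colinear or "
            "coplanar, sphere centre is underdetermined"
        )

    def ra(params: np.ndarray, centre: np.ndarray) -> np.ndarray:
        d = params - centre[None, :]
        return np.sqrt(4.0 * d[:, 0] ** 2 + d[:, 1] ** 2 + d[:, 2] ** 2)

    def resid(theta: np.ndarray) -> np.ndarray:
        return ra(pts, theta[:3]) / theta[3] - r_obs

    w = 1.0 / np.clip(r_obs, 0.05, None)
    starts = [(pts * w[:, None]).sum(axis=0) / w.sum()]
    starts.extend(pts)
    rng = np.random.default_rng(seed)
    centroid = pts.mean(axis=0)
    spread = max(pts.std(axis=0).mean(), 1.0)
    starts.extend(centroid + rng.normal(0.0, spread, size=3) for _ in range(n_random_starts))

    hi = pts.max() + 20.0
    best: tuple[float, np.ndarray, bool, str] | None = None
    for c0 in starts:
        c0 = np.clip(c0, 0.0, hi)
        r0_guess = float(np.median(ra(pts, c0) / np.clip(r_obs, 1e-6, None)))
        theta0 = np.array([*c0, max(r0_guess, 0.5)])
        try:
            sol = least_squares(
                resid,
                theta0,
                bounds=([0.0, 0.0, 0.0, 1e-3], [hi, hi, hi, 100.0]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            if best is None:
                best = (np.inf, theta0, False, str(exc))
            continue
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or rms < best[0]:
            best = (rms, sol.x, bool(sol.success), sol.message)
        if rms < 1e-10:
            break

    assert best is not None
    rms, theta, converged, message = best
    if not np.isfinite(rms):
        raise SphereFitError(f"sphere fit failed to converge: {message}")

    sphere = SoluteSphere(
        center=HansenParameters(*map(float, theta[:3])),
        radius_r0=float(theta[3]),
        label=observations[0].solute_label if observations else "",
    )
    residuals = {
        name: float(pred - obs)
        for name, pred, obs in zip(names, ra(pts, theta[:3]) / theta[3], r_obs)
    }
    return SphereFitResult(
        sphere=sphere, residuals=residuals, rms=rms, converged=converged, message=message
    )


def fit_red_panel(
    panel: Iterable[RedObservation],
    solvents: Mapping[str, HansenParameters],
    **kwargs,
) -> dict[str, SphereFitResult]:
    """Fit one sphere per solute label found in a mixed RED panel."""
    by_solute: dict[str, list[RedObservation]] = {}
    for obs in panel:
        by_solute.setdefault(obs.solute_label, []).append(obs)
    return {
        label: fit_solute_sphere(obs, solvents, **kwargs)
        for label, obs in by_solute.items()
    }


def evaporation_energy(s: SolventRecord, t_ref: float = 25.0) -> float:
    """Energy to heat 1 kg of solvent from t_ref to its boiling point and
    vaporize it, in kJ/kg: cp·(t_boil − t_ref) + dh_vap."""
    if s.cp is None or s.t_boil is None or s.dh_vap is None:
        raise ValueError(
            f"solvent {s.name!r} is missing cp, t_boil or dh_vap required for "
            "evaporation energy"
        )
    dt = s.t_boil - t_ref
    if dt < 0:
        warnings.warn(
            f"t_boil ({s.t_boil} °C) below reference ({t_ref} °C) for "
            f"{s.name!r}; sensible term clamped to 0",
            stacklevel=2,
        )
        dt = 0.0
    return s.cp * dt + s.dh_vap


def screening_report(
    solvents: Sequence[SolventRecord],
    spheres: Sequence[SoluteSphere],
    desirable: Sequence[str] = (),
    undesirable: Sequence[str] = (),
    reference: str | None = None,
    t_ref: float = 25.0,
) -> pd.DataFrame:
    """Rank solvents against a set of solute spheres.

    Returns one row per solvent with RED per solute, counts of desirable
    solutes dissolved (RED < 1), flags for undesirable solutes dissolved,
    evaporation energy and physical-property columns, and property ratios
    normalized to ``reference`` (ratio 1.0 for the reference itself).
    Missing properties yield NaN cells; the solvent row is kept.
    """
    sphere_by_label = {sp.label: sp for sp in spheres}
    for lbl in (*desirable, *undesirable):
        if lbl not in sphere_by_label:
            raise KeyError(f"no sphere supplied for solute {lbl!r}")

    rows = []
    for s in solvents:
        row: dict[str, object] = {"solvent": s.name}
        n_good = 0
        flagged: list[str] = []
        for sp in spheres:
            value = red(s.hansen, sp)
            row[f"red_{sp.label}"] = value
            cls = classify_red(value)
            if sp.label in desirable and cls == "good":
                n_good += 1
            if sp.label in undesirable and cls == "good":
                flagged.append(sp.label)
        row["n_desirable_good"] = n_good
        row["undesirable_dissolved"] = ",".join(flagged)
        try:
            row["evaporation_energy_kj_kg"] = evaporation_energy(s, t_ref)
        except ValueError:
            row["evaporation_energy_kj_kg"] = float("nan")
        row["t_melt_c"] = float("nan") if s.t_melt is None else s.t_melt
        row["t_boil_c"] = float("nan") if s.t_boil is None else s.t_boil
        row["viscosity_cp"] = float("nan") if s.viscosity is None else s.viscosity
        rows.append(row)

    frame = pd.DataFrame(rows).set_index("solvent")

    if reference is not None:
        if reference not in frame.index:
            raise KeyError(f"reference solvent {reference!r} not in report")
        for col in ("evaporation_energy_kj_kg", "t_boil_c", "viscosity_cp"):
            ref_val = frame.loc[reference, col]
            frame[f"{col}_vs_ref"] = frame[col] / ref_val

    return frame.sort_values(
        ["n_desirable_good", "evaporation_energy_kj_kg"],
        ascending=[False, True],
    )
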