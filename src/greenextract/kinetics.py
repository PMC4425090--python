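"""Solid-liquid extraction kinetics: sphere diffusion model and wash simulation.

The forward model is the classical series solution for diffusion out of a
sphere of radius ``rd``:

    (X_inf - X(t)) / (X_inf - X0) = sum_i 6/(i²π²) · exp(-i²π²·Deff·(t-t0)/rd²)

with ``X`` the cumulative extract yield (g extract per g dry matter), ``X0``
the starting accessibility (yield extrapolated to t = 0 from the diffusive
regime, i.e. the surface-washed fraction) and ``Deff`` the effective
diffusivity in m²/s.  Times are handled in minutes at the API surface and
converted to seconds internally so that the transfer coefficient ``k`` and
``Deff = k·rd²/π²`` come out in s⁻¹ and m²/s.

Fitting: the log-linearization of the leading series term (the paper-style
route, ``method="loglinear"``) is heavily biased when the sampling window sits
in the short-time multi-term regime, so the default ``method="series"`` uses
the log-linear estimate only to seed a full-series nonlinear least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_T0_MIN",
    "KineticDataset",
    "CrankFit",
    "WashingScenario",
    "WashSimulation",
    "UnfittableError",
    "crank_series_fraction",
    "crank_profile",
    "deff_from_k",
    "fit_crank",
    "starting_accessibility",
    "correct_for_sampling",
    "simulate_washes",
    "extrapolate_residual",
]

#: Reference time below which data belong to the convective washing stage.
DEFAULT_T0_MIN = 5.0


class UnfittableError(ValueError):
    """Raised when no valid points remain for a kinetic fit."""


@dataclass
class KineticDataset:
    """A measured (or synthetic) extraction time series.

    ``times_min`` in minutes since solvent contact, strictly increasing and
    non-negative; ``x`` in g extract per g dry matter.
    """

    times_min: np.ndarray
    x: np.ndarray
    rd_m: float
    temperature_c: float | None = None
    solvent_name: str | None = None
    x_inf_hint: float | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.x.shape:
            raise ValueError("times_min and x must be 1-D arrays of equal length")
        if self.times_min.size and self.times_min[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.x < 0):
            raise ValueError("yields must be >= 0")
        if not (self.rd_m > 0):
            raise ValueError(f"rd_m must be > 0, got {self.rd_m!r}")
        if self.x_inf_hint is not None and np.any(self.x > 1.1 * self.x_inf_hint):
            raise ValueError("yields exceed 110% of the supplied plateau hint")

    def __len__(self) -> int:
        return int(self.times_min.size)


@dataclass
class CrankFit:
    """Fitted diffusion-model parameters for one dataset."""

    x_inf: float
    x0: float
    t0_min: float
    k_per_s: float
    deff_m2_s: float
    r2: float
    n_points_used: int
    method: str = "series"

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 < self.x_inf):
            raise ValueError(f"need 0 <= x0 < x_inf, got x0={self.x0}, x_inf={self.x_inf}")
        if not (self.deff_m2_s > 0):
            raise ValueError(f"deff must be > 0, got {self.deff_m2_s!r}")


def crank_series_fraction(tau, n_terms: int = 200):
    """Remaining fraction S(τ) = Σ 6/(i²π²)·exp(-i²π²τ) for dimensionless
    time τ = Deff·(t-t0)/rd² >= 0.  Vectorized over τ; S(0) = 1 exactly."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("dimensionless time must be >= 0")
    i = np.arange(1, n_terms + 1, dtype=float)
    expo = -np.multiply.outer(i**2 * math.pi**2, tau_arr)
    s = (6.0 / (i**2 * math.pi**2)) @ np.exp(np.clip(expo, -745.0, 0.0)).reshape(
        n_terms, -1
    )
    s = s.reshape(tau_arr.shape)
    # the truncated partial sum undershoots the exact S(0) = 1
    s = np.where(tau_arr == 0.0, 1.0, s)
    return s if s.shape else float(s)


def s_zero(n_terms: int) -> float:
    """Partial sum Σ_{i<=n} 6/(i²π²); converges to 1 as n → ∞."""
    i = np.arange(1, n_terms + 1, dtype=float)
    return float(np.sum(6.0 / (i**2 * math.pi**2)))


def crank_profile(
    deff: float,
    rd: float,
    x_inf: float,
    x0: float,
    t0_min: float,
    times_min,
    n_terms: int = 200,
):
    """Forward yield profile x(t) for t >= t0 (minutes).

    x(t) = x_inf - (x_inf - x0)·S(Deff·(t-t0)/rd²).  Raises for requested
    times before t0, where the diffusion model is undefined.
    """
    if not (deff >= 0):
        raise ValueError(f"deff must be >= 0, got {deff!r}")
    if not (rd > 0):
        raise ValueError(f"rd must be > 0, got {rd!r}")
    t = np.asarray(times_min, dtype=float)
    if np.any(t < t0_min):
        raise ValueError(f"model undefined for t < t0 ({t0_min} min)")
    tau = deff * (t - t0_min) * 60.0 / rd**2
    out = x_inf - (x_inf - x0) * crank_series_fraction(tau, n_terms)
    return out if out.shape else float(out)


def deff_from_k(k: float, rd: float) -> float:
    """Effective diffusivity from the fitted transfer coefficient:
    Deff = k·rd²/π² (k in s⁻¹, rd in m, result in m²/s)."""
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k!r}")
    if not (rd > 0):
        raise ValueError(f"rd must be > 0, got {rd!r}")
    return k * rd**2 / math.pi**2


def _estimate_x_inf(ds: KineticDataset) -> float:
    if ds.x_inf_hint is not None:
        return float(ds.x_inf_hint)
    x = ds.x
    if len(x) >= 2 and x[-2] > 0 and abs(x[-1] - x[-2]) / x[-2] < 0.01:
        return float(np.mean(x[-2:]))
    warnings.warn(
        "no plateau detected (relative change of last two samples >= 1%); "
        "using max(x) as the plateau estimate",
        stacklevel=3,
    )
    return float(np.max(x))


def fit_crank(
    ds: KineticDataset,
    t0_min: float = DEFAULT_T0_MIN,
    *,
    x_inf: float | None = None,
    x0: float | None = None,
    method: str = "series",
    n_terms: int = 200,
) -> CrankFit:
    """Fit (k, Deff, X0) to a kinetic dataset using points with t > t0.

    ``method="loglinear"`` regresses ln(x_inf − x) on (t − t0): the slope is
    −k and the intercept back-extrapolates X0 (the value at t = t0, reported
    as the t = 0 accessibility).  When ``x0`` is supplied the regression is
    forced through the origin of ln((x_inf−x)/(x_inf−x0)), as the model
    equation has no intercept.

    ``method="series"`` (default) refines the log-linear seed by nonlinear
    least squares against the full multi-term series, which removes the
    single-term truncation bias on short-time data.
    """
    if method not in ("series", "loglinear"):
        raise ValueError(f"unknown method {method!r}")

    xi = float(x_inf) if x_inf is not None else _estimate_x_inf(ds)

    mask = ds.times_min > t0_min
    bad = mask & (ds.x >= xi)
    if np.any(bad):
        warnings.warn(
            f"dropping {int(bad.sum())} point(s) with x >= x_inf from the fit",
            stacklevel=2,
        )
        mask &= ds.x < xi
    if not np.any(mask):
        raise UnfittableError("no usable points with t > t0 and x < x_inf")
    t = ds.times_min[mask]
    xv = ds.x[mask]
    n_used = int(mask.sum())
    if n_used < 3:
        raise UnfittableError(f"kinetic fit needs >= 3 points after t0, got {n_used}")

    ts = (t - t0_min) * 60.0  # seconds

    if x0 is not None:
        if not (0.0 <= x0 < xi):
            raise ValueError("x0 must satisfy 0 <= x0 < x_inf")
        y = np.log((xi - xv) / (xi - x0))
        k = float(-(y @ ts) / (ts @ ts))  # through the origin
        x0_fit = float(x0)
    else:
        y = np.log(xi - xv)
        A = np.vstack([ts, np.ones_like(ts)]).T
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
        k = float(-slope)
        x0_fit = float(np.clip(xi - math.exp(intercept), 0.0, xi * (1 - 1e-9)))
    k = max(k, 1e-12)

    if method == "series":
        fit_x0 = x0 is None

        def model(log10_deff: float, x0v: float) -> np.ndarray:
            tau = 10.0**log10_deff * ts / ds.rd_m**2
            return xi - (xi - x0v) * crank_series_fraction(tau, n_terms)

        d_seed = float(np.clip(deff_from_k(k, ds.rd_m), 1e-14, 1e-8))
        if fit_x0:
            sol = least_squares(
                lambda p: model(p[0], p[1]) - xv,
                [math.log10(d_seed), x0_fit],
                bounds=([-14.0, 0.0], [-8.0, xi * (1 - 1e-9)]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            deff = 10.0 ** float(sol.x[0])
            x0_fit = float(sol.x[1])
        else:
            sol = least_squares(
                lambda p: model(p[0], x0_fit) - xv,
                [math.log10(d_seed)],
                bounds=([-14.0], [-8.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            deff = 10.0 ** float(sol.x[0])
        k = deff * math.pi**2 / ds.rd_m**2
        pred = model(math.log10(deff), x0_fit)
    else:
        deff = deff_from_k(k, ds.rd_m)
        pred = xi - (xi - x0_fit) * np.exp(-k * ts)

    ss_res = float(np.sum((xv - pred) ** 2))
    ss_tot = float(np.sum((xv - xv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return CrankFit(
        x_inf=xi,
        x0=x0_fit,
        t0_min=t0_min,
        k_per_s=k,
        deff_m2_s=deff,
        r2=r2,
        n_points_used=n_used,
        method=method,
    )


def starting_accessibility(
    ds: KineticDataset,
    t0_min: float = DEFAULT_T0_MIN,
    total_oil: float | None = None,
    **fit_kwargs,
) -> tuple[float, float | None]:
    """Starting accessibility X0 (g/g DM) and, when the total oil content is
    known, the fraction of total oil it represents (percent)."""
    fit = fit_crank(ds, t0_min, **fit_kwargs)
    pct = None if total_oil is None else 100.0 * fit.x0 / total_oil
    return fit.x0, pct


def correct_for_sampling(
    times_min,
    sample_masses_g,
    extract_fractions,
    initial_solvent_mass_g: float,
    dry_matter_mass_g: float,
    *,
    rd_m: float,
    temperature_c: float | None = None,
    solvent_name: str | None = None,
    x_inf_hint: float | None = None,
) -> KineticDataset:
    """Reconstruct cumulative extract yield from withdrawal measurements.

    At each draw the measured extract mass fraction of the sample and the
    sample mass are known.  The batch liquid loses both solvent and extract
    at every draw, so the cumulative extract produced at draw ``j`` is the
    extract currently in the flask plus everything already withdrawn:

        S_j = M0 - Σ_{i<j} m_i·(1 - f_i)        (solvent left)
        E_j = f_j·S_j / (1 - f_j)               (extract in flask)
        X_j = (E_j + Σ_{i<j} m_i·f_i) / m_DM

    With zero-mass draws this reduces to the naive concentration-to-yield
    conversion f·M0/((1-f)·m_DM).
    """
    t = np.asarray(times_min, dtype=float)
    m = np.asarray(sample_masses_g, dtype=float)
    f = np.asarray(extract_fractions, dtype=float)
    if not (t.shape == m.shape == f.shape):
        raise ValueError("times, masses and fractions must have equal length")
    if np.any(m < 0) or np.any((f < 0) | (f >= 1)):
        raise ValueError("sample masses must be >= 0 and fractions in [0, 1)")
    if not (initial_solvent_mass_g > 0 and dry_matter_mass_g > 0):
        raise ValueError("initial solvent and dry matter masses must be > 0")

    solvent_removed = 0.0
    extract_removed = 0.0
    x_out = np.empty_like(f)
    for j in range(f.size):
        s_flask = initial_solvent_mass_g - solvent_removed
        if s_flask <= 0:
            raise ValueError(
                "mass balance violated: cumulative withdrawals exceed the batch"
            )
        e_flask = f[j] * s_flask / (1.0 - f[j])
        x_out[j] = (e_flask + extract_removed) / dry_matter_mass_g
        solvent_removed += m[j] * (1.0 - f[j])
        extract_removed += m[j] * f[j]
    if initial_solvent_mass_g - solvent_removed <= 0:
        raise ValueError("mass balance violated: cumulative withdrawals exceed the batch")

    return KineticDataset(
        times_min=t,
        x=x_out,
        rd_m=rd_m,
        temperature_c=temperature_c,
        solvent_name=solvent_name,
        x_inf_hint=x_inf_hint,
    )


@dataclass
class WashingScenario:
    """Configuration of a multi-wash percolation extraction.

    ``retention`` is the miscella held by the drained solids between washes,
    either in kg liquid per kg dry matter (``retention_mode="mass"``) or in
    litres per tonne of dry matter (``retention_mode="volume"``, requires
    ``solvent_density`` in kg/L).
    """

    n_washes: int
    wash_duration_min: float
    solvent_to_solid: float  # kg fresh solvent per kg dry matter
    retention: float
    deff: float
    rd: float
    oil_content_initial: float  # g oil per g dry matter
    retention_mode: str = "mass"
    solvent_density: float | None = None
    n_terms: int = 400

    def __post_init__(self) -> None:
        if self.n_washes < 0:
            raise ValueError("n_washes must be >= 0")
        for name in ("wash_duration_min", "solvent_to_solid", "deff", "rd", "oil_content_initial"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.retention < 0:
            raise ValueError("retention must be >= 0")
        if self.retention_mode not in ("mass", "volume"):
            raise ValueError(f"retention_mode must be 'mass' or 'volume', got {self.retention_mode!r}")
        if self.retention_mode == "volume" and self.solvent_density is None:
            raise ValueError("volumetric retention requires solvent_density (kg/L)")

    @property
    def retention_kg_per_kg(self) -> float:
        if self.retention_mode == "mass":
            return self.retention
        return self.retention * self.solvent_density / 1000.0  # L/t DM -> kg/kg DM


@dataclass
class WashSimulation:
    """Per-wash ledger of a washing-stage simulation (basis: 1 kg dry matter)."""

    table: pd.DataFrame
    oil_initial: float

    @property
    def cumulative_recovery_pct(self) -> np.ndarray:
        return self.table["cumulative_recovery_pct"].to_numpy()

    @property
    def residual_pct(self) -> np.ndarray:
        return self.table["residual_oil_pct"].to_numpy()

    def washes_to_reach(self, recovery_pct: float) -> int | None:
        """Smallest wash count achieving the given cumulative recovery."""
        hit = np.nonzero(self.cumulative_recovery_pct >= recovery_pct)[0]
        return None if hit.size == 0 else int(hit[0]) + 1


def simulate_washes(sc: WashingScenario) -> WashSimulation:
    """Simulate sequential washes with retained-miscella carry-over.

    Each wash dissolves the fraction 1 − S(Deff·Δt/rd²) of the oil still held
    by the solid (ideal mixing: dissolved oil distributes over all liquid);
    draining then removes the fresh-solvent share of the liquid while the
    retained share carries its dissolved oil into the next wash.
    Oil is conserved exactly: recovered + in solid + in retained miscella
    equals the initial content after every wash.
    """
    ret = sc.retention_kg_per_kg
    fresh = sc.solvent_to_solid
    if ret >= fresh:
        raise ValueError(
            "retention >= available fresh solvent: the bed would flood "
            f"(retention {ret:.3g} kg/kg vs solvent {fresh:.3g} kg/kg)"
        )

    tau = sc.deff * sc.wash_duration_min * 60.0 / sc.rd**2
    phi = 1.0 - float(crank_series_fraction(tau, sc.n_terms))

    oil_solid = sc.oil_content_initial
    oil_retained = 0.0
    recovered = 0.0
    rows = []
    for wash in range(1, sc.n_washes + 1):
        liquid = fresh + ret
        dissolved_new = phi * oil_solid
        dissolved_total = oil_retained + dissolved_new
        drained_fraction = fresh / liquid
        out = dissolved_total * drained_fraction
        recovered += out
        oil_retained = dissolved_total * (1.0 - drained_fraction)
        oil_solid -= dissolved_new
        rows.append(
            {
                "wash": wash,
                "dissolved_this_wash": dissolved_new,
                "recovered_this_wash": out,
                "recovered_this_wash_pct": 100.0 * out / sc.oil_content_initial,
                "cumulative_recovery_pct": 100.0 * recovered / sc.oil_content_initial,
                "oil_in_solid": oil_solid,
                "oil_in_retained_miscella": oil_retained,
                "residual_oil_pct": 100.0
                * (oil_solid + oil_retained)
                / sc.oil_content_initial,
                "mass_balance_error": (recovered + oil_solid + oil_retained)
                - sc.oil_content_initial,
            }
        )

    columns = [
        "wash",
        "dissolved_this_wash",
        "recovered_this_wash",
        "recovered_this_wash_pct",
        "cumulative_recovery_pct",
        "oil_in_solid",
        "oil_in_retained_miscella",
        "residual_oil_pct",
        "mass_balance_error",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return WashSimulation(table=table, oil_initial=sc.oil_content_initial)


def extrapolate_residual(
    industry_residual_kg_per_t: float,
    pilot_residual_ref_pct: float,
    pilot_residual_alt_pct: float,
) -> tuple[float, float]:
    """Project an industrial meal residual under the alternative solvent.

    Scales the industry residual by the pilot residual ratio (alt/ref) and
    returns (projected residual kg/t, oil gain kg/t).
    """
    if not (pilot_residual_ref_pct > 0):
        raise ValueError("pilot_residual_ref_pct must be > 0")
    projected = industry_residual_kg_per_t * pilot_residual_alt_pct / pilot_residual_ref_pct
    return projected, industry_residual_kg_per_t - projected
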