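"""Loaders for the packaged reference tables and default configurations.

All fixtures live as plain CSV/YAML under ``greenextract/data``; every loader
also accepts an explicit path so user files in the same dialects can be read
with the same code paths.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .composition import FattyAcidProfile, Measurement, TocopherolPanel
from .economics import EconomicAssumptions
from .energy import ProcessScenario, SteamProperties
from .hsp import HansenParameters, RedObservation, SolventRecord
from .kinetics import KineticDataset, WashingScenario

__all__ = [
    "data_path",
    "load_solvents",
    "load_red_panel",
    "load_fatty_acid_profile",
    "load_sterols",
    "load_tocopherols",
    "load_scenario",
    "load_economics",
    "load_washes_config",
    "load_kinetics_defaults",
    "load_residual_extrapolation",
    "read_kinetics_csv",
    "write_kinetics_csv",
]

_SOLVENT_SETS = {
    "default": "solvents.csv",
    "sphere_fit": "solvents_sphere_fit.csv",
    "cal_converted": "solvents_cal_converted.csv",
}


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    path = resources.files("greenextract").joinpath("data", name)
    return Path(str(path))


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def load_solvents(source: str | Path = "default") -> dict[str, SolventRecord]:
    """Load a solvent property table into records keyed by name.

    ``source`` may be one of the packaged sets (``default``, ``sphere_fit``,
    ``cal_converted``) or a path to a CSV with the same header.
    """
    path = data_path(_SOLVENT_SETS[source]) if source in _SOLVENT_SETS else Path(source)
    frame = pd.read_csv(path)
    out: dict[str, SolventRecord] = {}
    for row in frame.itertuples(index=False):
        out[row.name] = SolventRecord(
            name=row.name,
            hansen=HansenParameters(row.delta_d, row.delta_p, row.delta_h),
            cp=_opt(row.cp),
            t_boil=_opt(row.t_boil),
            dh_vap=_opt(row.dh_vap),
            density=_opt(row.density),
            t_melt=_opt(row.t_melt),
            viscosity=_opt(row.viscosity),
            price=_opt(row.price),
        )
    return out


def load_red_panel(path: str | Path | None = None) -> list[RedObservation]:
    """Load a RED panel CSV (``solvent,solute,red``)."""
    frame = pd.read_csv(data_path("red_panel.csv") if path is None else path)
    return [
        RedObservation(str(r.solvent), str(r.solute), float(r.red))
        for r in frame.itertuples(index=False)
    ]


def _read_measurement_table(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "censored_limit" not in frame.columns:
        frame["censored_limit"] = np.nan
    return frame


def _row_measurement(row) -> Measurement:
    if not pd.isna(row.censored_limit):
        return Measurement(
            mean=float(row.censored_limit), below_limit=True, n=int(row.n)
        )
    return Measurement(
        mean=float(row.mean),
        sd=_opt(row.sd),
        n=None if pd.isna(row.n) else int(row.n),
    )


def load_fatty_acid_profile(solvent: str = "methf", path: str | Path | None = None) -> FattyAcidProfile:
    """Packaged fatty-acid profile for ``"hexane"`` or ``"methf"``, or any
    CSV in the ``analyte,mean,sd,n,unit`` dialect."""
    if path is None:
        path = data_path(f"fatty_acids_{solvent}.csv")
    frame = _read_measurement_table(Path(path))
    entries: dict[str, Measurement] = {}
    yield_meas = None
    for row in frame.itertuples(index=False):
        if row.analyte == "extraction_yield":
            yield_meas = _row_measurement(row)
        else:
            entries[row.analyte] = _row_measurement(row)
    return FattyAcidProfile(entries=entries, yield_g_per_100g=yield_meas, name=str(solvent))


def load_sterols(solvent: str = "methf", path: str | Path | None = None) -> pd.DataFrame:
    """Sterol composition table (percent of identified sterols, plus the
    total row in mg/100 g); censored rows keep their limit."""
    if path is None:
        path = data_path(f"sterols_{solvent}.csv")
    return _read_measurement_table(Path(path))


def load_tocopherols(solvent: str = "methf", path: str | Path | None = None) -> TocopherolPanel:
    """Tocopherol/tocotrienol panel in mg/kg fat."""
    if path is None:
        path = data_path(f"tocopherols_{solvent}.csv")
    frame = _read_measurement_table(Path(path))
    by_name = {row.analyte: _row_measurement(row) for row in frame.itertuples(index=False)}
    tocotrienols = {
        name.removesuffix("_tocotrienol"): meas
        for name, meas in by_name.items()
        if name.endswith("_tocotrienol")
    }
    return TocopherolPanel(
        alpha=by_name["alpha_tocopherol"],
        beta=by_name["beta_tocopherol"],
        gamma=by_name["gamma_tocopherol"],
        delta=by_name["delta_tocopherol"],
        tocotrienols=tocotrienols,
        name=str(solvent),
    )


def load_scenario(
    source: str | Path,
    solvents: Mapping[str, SolventRecord] | None = None,
) -> tuple[ProcessScenario, SteamProperties]:
    """Load a process scenario YAML (packaged ``hexane``/``methf`` or a path).

    The YAML names its solvent; the record is resolved against the packaged
    solvent table unless ``solvents`` is given.
    """
    if source in ("hexane", "methf"):
        path = data_path(f"energy_{source}.yml")
    else:
        path = Path(source)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if solvents is None:
        solvents = load_solvents()
    try:
        solvent = solvents[cfg.pop("solvent")]
    except KeyError as exc:
        raise ValueError(f"scenario configuration error: unknown solvent {exc}") from None
    steam = SteamProperties(**cfg.pop("steam", {}))
    return ProcessScenario(solvent=solvent, **cfg), steam


def load_economics(path: str | Path | None = None) -> EconomicAssumptions:
    with open(data_path("economics.yml") if path is None else path) as fh:
        return EconomicAssumptions(**yaml.safe_load(fh))


def load_washes_config(path: str | Path | None = None) -> dict:
    """Washing-stage defaults; build per-solvent scenarios with
    :func:`washing_scenario_from_config`."""
    with open(data_path("washes.yml") if path is None else path) as fh:
        return yaml.safe_load(fh)


def washing_scenario_from_config(cfg: dict, which: str = "ref") -> WashingScenario:
    deff = cfg[f"deff_{which}"]
    return WashingScenario(
        n_washes=int(cfg["n_washes"]),
        wash_duration_min=float(cfg["wash_duration_min"]),
        solvent_to_solid=float(cfg["solvent_to_solid"]),
        retention=float(cfg["retention"]),
        retention_mode=cfg.get("retention_mode", "mass"),
        deff=float(deff),
        rd=float(cfg["rd"]),
        oil_content_initial=float(cfg["oil_content_initial"]),
        solvent_density=cfg.get("solvent_density"),
    )


def load_kinetics_defaults(path: str | Path | None = None) -> dict:
    with open(data_path("kinetics_defaults.yml") if path is None else path) as fh:
        return yaml.safe_load(fh)


def load_residual_extrapolation(path: str | Path | None = None) -> dict:
    with open(data_path("residual_extrapolation.yml") if path is None else path) as fh:
        return yaml.safe_load(fh)


def read_kinetics_csv(path: str | Path) -> KineticDataset:
    """Read a kinetic CSV: ``time_min,x_g_per_gDM`` with ``# key=value``
    metadata header lines (rd_m mandatory)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(pd.io.common.StringIO("".join(lines[body_start:])))
    if "rd_m" not in meta:
        raise ValueError(f"kinetic CSV {path} lacks the mandatory '# rd_m=' header")
    return KineticDataset(
        times_min=frame["time_min"].to_numpy(float),
        x=frame["x_g_per_gDM"].to_numpy(float),
        rd_m=float(meta["rd_m"]),
        temperature_c=float(meta["temperature_C"]) if "temperature_C" in meta else None,
        solvent_name=meta.get("solvent"),
        x_inf_hint=float(meta["x_inf"]) if "x_inf" in meta else None,
    )


def write_kinetics_csv(ds: KineticDataset, path: str | Path) -> None:
    """Write a dataset in the dialect read by :func:`read_kinetics_csv`."""
    with open(path, "w") as fh:
        fh.write(f"# rd_m={ds.rd_m!r}\n")
        if ds.solvent_name is not None:
            fh.write(f"# solvent={ds.solvent_name}\n")
        if ds.temperature_c is not None:
            fh.write(f"# temperature_C={ds.temperature_c!r}\n")
        if ds.x_inf_hint is not None:
            fh.write(f"# x_inf={ds.x_inf_hint!r}\n")
        fh.write("time_min,x_g_per_gDM\n")
        for t, x in zip(ds.times_min, ds.x):
            fh.write(f"{float(t)!r},{float(x)!r}\n")
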