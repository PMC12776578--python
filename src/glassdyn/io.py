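"""CSV/JSON readers and writers plus run configuration.

CSV dialect everywhere: comma-separated, period decimal, UTF-8, mandatory
header.  Temperatures are stored in Kelvin internally for spectra; files
declare the unit through the column name (``temperature_K`` or
``temperature_C``) — both present is an ambiguity error, never a guess.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .bds import DielectricSpectrum, RelaxationMap
from .dsc import EnthalpyRecoverySeries, Thermogram
from .errors import DataError, SchemaError
from .kinetics import GrowthTrack, StorageSeries

__all__ = [
    "RunConfig",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_thermogram_csv",
    "write_thermogram_csv",
    "read_growth_tracks_csv",
    "read_recovery_csv",
    "read_storage_csv",
    "read_nucleation_csv",
    "write_relaxation_map_csv",
    "write_report",
    "to_jsonable",
]


class ModeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    delta_eps: float
    tau_hn: float
    a: float = 0.5
    b: float = 1.0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    sample: Optional[str] = None
    seed: int = 1
    temperature_unit: Optional[str] = None  # "K" | "C"
    scan_rate: float = 10.0
    exo_up: bool = True
    mass_mg: Optional[float] = None
    tg_C: Optional[float] = None
    ta_C: Optional[float] = None
    delta_cp: Optional[float] = None
    rho_g_cm3: Optional[float] = None
    cpg: Optional[float] = None
    cpl: Optional[float] = None
    centers_init: Optional[list[float]] = None
    modes: Optional[list[ModeSpec]] = None
    fit_sigma: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def _temperature_kelvin(df: pd.DataFrame, path) -> pd.Series:
    has_k = "temperature_K" in df.columns
    has_c = "temperature_C" in df.columns
    if has_k and has_c:
        raise SchemaError(f"{path}: both temperature_K and temperature_C present (ambiguous)")
    if has_k:
        return df["temperature_K"].astype(float)
    if has_c:
        return df["temperature_C"].astype(float) + 273.15
    raise SchemaError(f"{path}: need a temperature_K or temperature_C column")


def read_spectra_csv(path) -> list[DielectricSpectrum]:
    """Long-form spectra: sample, temperature_K|_C, frequency_Hz, eps_real, eps_imag."""
    df = pd.read_csv(path)
    _require(df, ["sample", "frequency_Hz", "eps_real", "eps_imag"], path)
    df = df.assign(_TK=_temperature_kelvin(df, path))
    out = []
    for (sample, tk), grp in df.groupby(["sample", "_TK"], sort=True):
        grp = grp.sort_values("frequency_Hz")
        f = grp["frequency_Hz"].to_numpy(float)
        dup = np.flatnonzero(np.diff(f) <= 0)
        if dup.size:
            row = int(grp.index[dup[0] + 1])
            raise DataError(f"{path}: non-monotone frequency at row {row}")
        out.append(DielectricSpectrum(
            temperature=float(tk), freq=f,
            eps_real=grp["eps_real"].to_numpy(float),
            eps_imag=grp["eps_imag"].to_numpy(float),
            sample=str(sample),
        ))
    return out


def write_spectra_csv(specs: Sequence[DielectricSpectrum], path) -> None:
    frames = [
        pd.DataFrame({
            "sample": s.sample, "temperature_K": s.temperature,
            "frequency_Hz": s.freq, "eps_real": s.eps_real, "eps_imag": s.eps_imag,
        })
        for s in specs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_thermogram_csv(path, scan_rate: float = 10.0, exo_up: bool = True) -> list[Thermogram]:
    """DSC traces: sample, channel, temperature_C, heat_flow (W/g)."""
    df = pd.read_csv(path)
    _require(df, ["sample", "channel", "temperature_C", "heat_flow"], path)
    out = []
    for (sample, channel), grp in df.groupby(["sample", "channel"], sort=True):
        out.append(Thermogram(
            temperature=grp["temperature_C"].to_numpy(float),
            heat_flow=grp["heat_flow"].to_numpy(float),
            channel=str(channel), scan_rate=scan_rate, exo_up=exo_up,
            sample=str(sample),
        ))
    return out


def write_thermogram_csv(traces: Sequence[Thermogram], path) -> None:
    frames = [
        pd.DataFrame({
            "sample": t.sample, "channel": t.channel,
            "temperature_C": t.temperature, "heat_flow": t.heat_flow,
        })
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_growth_tracks_csv(path) -> list[GrowthTrack]:
    """Growth tracks: direction, time_s, radius_um."""
    df = pd.read_csv(path)
    _require(df, ["direction", "time_s", "radius_um"], path)
    out = []
    for direction, grp in df.groupby("direction", sort=True):
        grp = grp.sort_values("time_s")
        out.append(GrowthTrack(
            direction=int(direction),
            time_s=grp["time_s"].to_numpy(float),
            radius_um=grp["radius_um"].to_numpy(float),
        ))
    return out


def read_recovery_csv(path, ta_C: float) -> EnthalpyRecoverySeries:
    """Enthalpy-recovery table: t_min, dh_J_per_g."""
    df = pd.read_csv(path)
    _require(df, ["t_min", "dh_J_per_g"], path)
    df = df.sort_values("t_min")
    return EnthalpyRecoverySeries(
        ta=ta_C, t_min=df["t_min"].to_numpy(float), dh=df["dh_J_per_g"].to_numpy(float)
    )


def read_storage_csv(path) -> list[StorageSeries]:
    """Storage series: sample, storage_temp_C, days, t_onset_C, enthalpy_J_per_g, glass_fraction."""
    df = pd.read_csv(path)
    _require(df, ["sample", "storage_temp_C", "days", "t_onset_C",
                  "enthalpy_J_per_g", "glass_fraction"], path)
    out = []
    for (sample, st), grp in df.groupby(["sample", "storage_temp_C"], sort=True):
        grp = grp.sort_values("days")
        out.append(StorageSeries(
            sample=str(sample), storage_temp=float(st),
            days=grp["days"].to_numpy(float),
            t_onset=grp["t_onset_C"].to_numpy(float),
            enthalpy=grp["enthalpy_J_per_g"].to_numpy(float),
            glass_fraction=grp["glass_fraction"].to_numpy(float),
        ))
    return out


def read_nucleation_csv(path) -> pd.DataFrame:
    """Nucleation assay outcomes: ta_C, crystallized (0/1), enthalpy_J_per_g, t_onset_C."""
    df = pd.read_csv(path)
    _require(df, ["ta_C", "crystallized"], path)
    return df


def write_relaxation_map_csv(rmap: RelaxationMap, path) -> None:
    rows = []
    for process, arr in rmap.processes.items():
        for T, tau, de in arr:
            rows.append({"process": process, "T_K": T, "tau_s": tau, "delta_eps": de})
    pd.DataFrame(rows).to_csv(path, index=False)


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy / containers to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results, path) -> None:
    """Write any result structure as an indented JSON report."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
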