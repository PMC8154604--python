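"""Delimited-text interchange formats and structured configuration.

Everything the pipeline reads or writes is plain text: CSV tables with
unit-suffixed column names, trajectory series as CSV with ``# key:
value`` metadata header lines, and a YAML configuration file with
``constants``, ``dielectric``, ``viscosity`` and ``interface`` sections
whose keys carry explicit units.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .constitutive import (
    Combination,
    DielectricModel,
    InterfaceSpec,
    ProfileMode,
    ViscosityModel,
)
from .double_layer import DoubleLayerSolution
from .estimators import TrajectorySeries
from .fitting import FitResult, MeasurementTable

__all__ = [
    "read_measurement_table",
    "write_measurement_table",
    "read_trajectory",
    "write_trajectory",
    "write_profile_table",
    "write_fit_report",
    "load_config",
    "models_from_config",
    "DEFAULT_CONFIG",
    "write_manifest",
]


def write_measurement_table(table: MeasurementTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_measurement_table(path) -> MeasurementTable:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse measurement table {path}: {exc}") from exc
    return MeasurementTable(df)


def write_trajectory(series: TrajectorySeries, path) -> None:
    """Trajectory series as CSV with metadata header comments."""
    with open(path, "w") as fh:
        fh.write(f"# volume_nm3: {series.volume!r}\n")
        fh.write(f"# temperature_K: {series.temperature!r}\n")
        fh.write(f"# dt_ps: {series.dt!r}\n")
        fh.write(f"# field_V_per_nm: {series.applied_field!r}\n")
        fh.write(f"# field_direction: {series.field_direction}\n")
        fh.write(f"# columns: {','.join(series.labels)}\n")
        np.savetxt(fh, series.samples, delimiter=",",
                   header=",".join(series.labels), comments="")


def read_trajectory(path) -> TrajectorySeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    labels = tuple(meta.get("columns", ",".join(df.columns)).split(","))
    return TrajectorySeries(
        dt=float(meta["dt_ps"]),
        samples=df[list(labels)].to_numpy(dtype=float),
        volume=float(meta["volume_nm3"]),
        temperature=float(meta.get("temperature_K", 300.0)),
        labels=labels,
        field_direction=meta.get("field_direction", "x"),
        applied_field=float(meta.get("field_V_per_nm", 0.0)),
    )


def write_profile_table(dl: DoubleLayerSolution, path, eta=None) -> None:
    """Double-layer profiles as a delimited-text table."""
    df = pd.DataFrame({
        "z_nm": dl.z_grid,
        "psi": dl.psi,
        "E_V_per_nm": dl.E_field,
        "c_plus_M": dl.c_plus,
        "c_minus_M": dl.c_minus,
        "eps_bar": dl.eps_bar,
        "D_e_per_nm2": dl.displacement,
    })
    if eta is not None:
        df["eta_mPas"] = eta
    df.to_csv(path, index=False)


def write_fit_report(result: FitResult, path) -> None:
    """Machine-readable fit report (JSON) with parameters and stderr."""
    names = list(result.params)
    payload = {
        "model": result.model_tag,
        "params": result.params,
        "stderr": {n: float(np.sqrt(result.cov[i, i]))
                   for i, n in enumerate(names)},
        "fixed": result.fixed,
        "rss": result.rss,
        "n_points": result.n_points,
        "at_boundary": result.at_boundary,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "constants": {
        "temperature_K": 300.0,
        "thermal_voltage_V": 0.025852,
    },
    "dielectric": {
        "eps_w": 71.0,
        "eps_ms": 27.9,
        "alpha_per_M": -11.59,
        # no published values exist for the two saturation parameters below;
        # they are documented placeholders, not literature numbers
        "eps_n": 4.0,
        "a_E_nm_per_V": 10.0,
        "combination": "multiplicative",
    },
    "viscosity": {
        "eta_w_mPas": 0.648,
        "a_c1_mPas_per_M": 0.0777,
        "a_c2_mPas_per_M2": 0.0223,
        "a_E1_par_mPas": 0.160,
        "a_E2_par_mPas_nm2_per_V2": 0.0868,
        "a_E1_perp_mPas": -0.190,
        "a_E2_perp_mPas_nm2_per_V2": 0.0319,
        "p0_e_nm": 0.049,
        "combination": "multiplicative",
    },
    "interface": {
        "sigma0_e_per_nm2": 0.1,
        "c0_M": 0.01,
        "d_nm": 0.3,
        "z_int_nm": 0.44,
        "eps_int": 4.4,
        "eta_int_over_eta_w": 3.7,
        "b_s_nm": -0.32,
        "profile_mode": "extended_box",
        "E_ext_V_per_nm": 0.3,
    },
}


def load_config(path=None) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    cfg = {sect: dict(vals) for sect, vals in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for sect, vals in user.items():
            if sect not in cfg:
                raise ValueError(f"unknown config section {sect!r}")
            for key, val in (vals or {}).items():
                if key not in cfg[sect]:
                    raise ValueError(f"unknown config key {sect}.{key}")
                cfg[sect][key] = val
    return cfg


def models_from_config(cfg: dict):
    """Build (constants, dielectric, viscosity, interface) from a config."""
    cc = cfg["constants"]
    constants = PhysicalConstants(temperature=cc["temperature_K"],
                                  thermal_voltage=cc["thermal_voltage_V"])
    dd = cfg["dielectric"]
    dielectric = DielectricModel(
        eps_w=dd["eps_w"], eps_ms=dd["eps_ms"], alpha=dd["alpha_per_M"],
        eps_n=dd["eps_n"], a_E=dd["a_E_nm_per_V"],
        combination=Combination(dd["combination"]))
    vv = cfg["viscosity"]
    viscosity = ViscosityModel(
        eta_w=vv["eta_w_mPas"], a_c1=vv["a_c1_mPas_per_M"],
        a_c2=vv["a_c2_mPas_per_M2"],
        a_E1_par=vv["a_E1_par_mPas"], a_E2_par=vv["a_E2_par_mPas_nm2_per_V2"],
        a_E1_perp=vv["a_E1_perp_mPas"],
        a_E2_perp=vv["a_E2_perp_mPas_nm2_per_V2"],
        p0=vv["p0_e_nm"], combination=Combination(vv["combination"]),
        constants=constants)
    ii = cfg["interface"]
    interface = InterfaceSpec(
        sigma0=ii["sigma0_e_per_nm2"], c0=ii["c0_M"], d=ii["d_nm"],
        z_int=ii["z_int_nm"], eps_int=ii["eps_int"],
        eta_int=ii["eta_int_over_eta_w"] * vv["eta_w_mPas"],
        b_s=ii["b_s_nm"], profile_mode=ProfileMode(ii["profile_mode"]),
        E_ext=ii["E_ext_V_per_nm"])
    return constants, dielectric, viscosity, interface


def write_manifest(out_dir, *, seed=None, config: dict | None = None,
                   extra: dict | None = None) -> Path:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__
    cfg = config or DEFAULT_CONFIG
    blob = json.dumps(cfg, sort_keys=True).encode()
    payload = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "config": cfg,
    }
    if extra:
        payload.update(extra)
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    return out
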