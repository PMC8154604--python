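"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here from a
stated truth model plus controlled noise: bulk measurement tables of the
dielectric constant and viscosity on an (E0, c0) grid, stationary
Gaussian polarization series for the fluctuation estimator,
Ornstein--Uhlenbeck stress series whose Green--Kubo integral equals a
prescribed viscosity, and saturating channel velocity profiles for the
plateau extractor.

The series emulate the *statistical structure* of molecular-dynamics
outputs (stationarity, a single correlation time, symmetric Gaussian
noise), not their microscopic detail.

Seeding is counter-based: every generator derives an independent stream
from (seed, generator-name), so adding a generator never perturbs the
output of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .constitutive import (
    Component,
    DielectricModel,
    ViscosityModel,
    eps_combined,
    eta_combined,
)
from .estimators import STRESS_COMPONENTS, TrajectorySeries
from .fitting import MeasurementTable

__all__ = [
    "SyntheticConfig",
    "rng_for",
    "gen_dielectric_table",
    "gen_viscosity_table",
    "gen_polarization_series",
    "gen_stress_series",
    "gen_velocity_profile",
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic stream for (seed, generator-name)."""
    tag = zlib.crc32(name.encode("utf-8"))  # stable across sessions
    return np.random.default_rng([int(seed), int(tag)])


@dataclass
class SyntheticConfig:
    """Grids, noise levels and truth models for the table generators."""

    seed: int
    E0_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0)      # V/nm
    c0_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)  # M
    noise_eps: float = 0.0      # absolute Gaussian sd on dielectric values
    noise_eta: float = 0.0      # mPa s
    n_samples: int = 100_000
    dt: float = 0.02            # ps
    tau_c: float = 0.2          # ps, OU correlation time
    dielectric: DielectricModel = field(default_factory=DielectricModel)
    viscosity: ViscosityModel = field(default_factory=ViscosityModel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if len(self.E0_grid) == 0 or len(self.c0_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.noise_eps < 0 or self.noise_eta < 0:
            raise ValueError("noise levels must be non-negative")


def gen_dielectric_table(cfg: SyntheticConfig) -> MeasurementTable:
    """Dielectric difference constant on the (E0, c0) grid plus noise."""
    rng = rng_for(cfg.seed, "dielectric_table")
    rows = []
    for E0 in cfg.E0_grid:
        for c0 in cfg.c0_grid:
            truth = float(eps_combined(E0, c0, cfg.dielectric))
            val = truth + (rng.normal(0.0, cfg.noise_eps) if cfg.noise_eps else 0.0)
            rows.append({
                "E0_V_per_nm": float(E0), "c0_M": float(c0),
                "component": "parallel", "quantity": "eps_diff",
                "value": val,
                "stderr": cfg.noise_eps if cfg.noise_eps else np.nan,
            })
    return MeasurementTable(pd.DataFrame(rows))


def gen_viscosity_table(cfg: SyntheticConfig) -> MeasurementTable:
    """Viscosity components on the (E0, c0) grid plus noise."""
    rng = rng_for(cfg.seed, "viscosity_table")
    rows = []
    for comp in (Component.PARALLEL, Component.PERPENDICULAR):
        for E0 in cfg.E0_grid:
            for c0 in cfg.c0_grid:
                truth = float(eta_combined(E0, c0, comp, cfg.viscosity))
                val = truth + (rng.normal(0.0, cfg.noise_eta)
                               if cfg.noise_eta else 0.0)
                rows.append({
                    "E0_V_per_nm": float(E0), "c0_M": float(c0),
                    "component": comp.value, "quantity": "eta",
                    "value": val,
                    "stderr": cfg.noise_eta if cfg.noise_eta else np.nan,
                })
    return MeasurementTable(pd.DataFrame(rows))


def gen_polarization_series(
    target_eps: float,
    volume: float,
    temperature: float = 300.0,
    n: int = 100_000,
    dt: float = 0.01,
    seed: int = 0,
    applied_field: float = 0.0,
    target_eps_diff: float | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> TrajectorySeries:
    """Gaussian polarization series with prescribed dielectric constant.

    Component variance is (target_eps - 1) eps0 V kT so the fluctuation
    estimator recovers ``target_eps``.  If ``applied_field`` > 0 the
    field-direction component additionally carries the mean
    (target_eps_diff - 1) eps0 V E0, feeding the mean-polarization
    estimator of the difference constant.
    """
    if target_eps < 1.0:
        raise ValueError("target_eps must be >= 1")
    rng = rng_for(seed, "polarization_series")
    kT = constants.kT_eV * temperature / constants.temperature
    var = (target_eps - 1.0) * constants.eps0 * volume * kT
    samples = rng.normal(0.0, np.sqrt(var) if var > 0 else 0.0, size=(n, 3))
    if applied_field > 0:
        eps_d = target_eps if target_eps_diff is None else target_eps_diff
        samples[:, 0] += (eps_d - 1.0) * constants.eps0 * volume * applied_field
    return TrajectorySeries(dt=dt, samples=samples, volume=volume,
                            temperature=temperature, labels=("x", "y", "z"),
                            field_direction="x", applied_field=applied_field,
                            constants=constants)


def gen_stress_series(
    target_eta: float,
    tau_c: float,
    volume: float,
    temperature: float = 300.0,
    n: int = 1_000_000,
    dt: float = 0.02,
    seed: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> TrajectorySeries:
    """Six independent OU stress components with a prescribed viscosity.

    Each component has autocovariance C0 exp(-tau/tau_c) with
    C0 = target_eta kT/(V tau_c) (in bar^2 after unit conversion), so the
    Green--Kubo integral of every component converges to ``target_eta``.
    """
    if target_eta <= 0:
        raise ValueError("target_eta must be positive")
    if dt >= tau_c:
        raise ValueError("dt must resolve the correlation time (dt < tau_c)")
    rng = rng_for(seed, "stress_series")
    kT_J = constants.kT_joule * temperature / constants.temperature
    # C0 in bar^2: eta = (V/kT) C0 tau_c * GREEN_KUBO_TO_MPAS
    c0_bar2 = target_eta * kT_J / (volume * tau_c * constants.GREEN_KUBO_TO_MPAS)
    rho = np.exp(-dt / tau_c)
    innov_sd = np.sqrt(c0_bar2 * (1.0 - rho**2))
    # exact stationary OU discretization x_i = rho x_{i-1} + shock_i,
    # run as an AR(1) filter over a stationary initial draw
    e = np.empty((n, 6))
    e[0] = rng.normal(0.0, np.sqrt(c0_bar2), size=6)
    e[1:] = rng.normal(0.0, innov_sd, size=(n - 1, 6))
    x = lfilter([1.0], [1.0, -rho], e, axis=0)
    return TrajectorySeries(dt=dt, samples=x, volume=volume,
                            temperature=temperature,
                            labels=STRESS_COMPONENTS,
                            field_direction="x", constants=constants)


def gen_velocity_profile(
    u_inf: float,
    decay_length: float,
    z_max: float,
    n: int = 600,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Saturating channel velocity profile u(z) = u_inf (1 - exp(-z/l))."""
    if z_max <= 5 * decay_length:
        raise ValueError("z_max must exceed 5 decay lengths for a plateau")
    rng = rng_for(seed, "velocity_profile")
    z = np.linspace(0.0, z_max, n)
    u = u_inf * (1.0 - np.exp(-z / decay_length))
    if noise > 0:
        u = u + rng.normal(0.0, noise, size=n)
    return pd.DataFrame({"z_nm": z, "u_nm_per_ns": u})
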