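"""Dielectric and viscosity estimators for trajectory time series.

These are the statistical-mechanics estimators a bulk molecular-dynamics
analysis would apply, here exercised on synthetic series with known
ground truth:

* static dielectric constant from equilibrium polarization fluctuations
  (fluctuation--dissipation: eps = 1 + var(M)/(eps0 V kT), with the
  high-frequency constant fixed at 1),
* dielectric *difference* constant at finite applied field from the mean
  polarization (epsbar = 1 + <M>/(eps0 V E0)),
* differential dielectric constant from a finite difference of two slab
  states at different applied displacement fields,
* shear viscosity from the Green--Kubo integral of off-diagonal stress
  autocorrelations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "TrajectorySeries",
    "SlabStatePair",
    "STRESS_COMPONENTS",
    "eps_from_fluctuations",
    "eps_diff_from_mean_polarization",
    "eps_slab_finite_difference",
    "autocorrelation",
    "viscosity_green_kubo",
]

#: off-diagonal stress component labels; field along x splits them into a
#: parallel set (one index along the field) and a perpendicular set
STRESS_COMPONENTS = ("xy", "yx", "xz", "zx", "yz", "zy")
PARALLEL_SET = ("xz", "zx", "xy", "yx")
PERPENDICULAR_SET = ("yz", "zy")


@dataclass
class TrajectorySeries:
    """Time-ordered samples of polarization (e nm) or stress (bar).

    ``samples`` has shape (n, k): k = 3 polarization components labelled
    by axis, or k = 6 off-diagonal stress components labelled by
    ``STRESS_COMPONENTS``.
    """

    dt: float                      # ps
    samples: np.ndarray            # (n, k)
    volume: float                  # nm^3
    temperature: float = 300.0     # K
    labels: tuple[str, ...] = ("x", "y", "z")
    field_direction: str = "x"
    applied_field: float = 0.0     # V/nm
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] < 2:
            raise ValueError("a trajectory series needs at least 2 samples")
        if self.dt <= 0 or self.volume <= 0:
            raise ValueError("dt and volume must be positive")
        if len(self.labels) != self.samples.shape[1]:
            raise ValueError("one label per sample column is required")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Series duration in ps."""
        return (self.n - 1) * self.dt

    def column(self, label: str) -> np.ndarray:
        try:
            return self.samples[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no column labelled {label!r}") from None


@dataclass(frozen=True)
class SlabStatePair:
    """Two slab states at different applied displacement fields.

    D is set by the plate charge (e/nm^2); E_mid is the measured electric
    field at the channel center (V/nm).
    """

    D_low: float
    D_high: float
    E_mid_low: float
    E_mid_high: float

    def __post_init__(self) -> None:
        if self.D_low == self.D_high:
            raise ValueError("the two slab states must differ in D")


def _fluct_norm(series: TrajectorySeries) -> float:
    c = series.constants
    # kT in e V so that (e nm)^2 / (e/(V nm) * nm^3 * e V) is dimensionless
    return c.eps0 * series.volume * c.kT_eV * (series.temperature / c.temperature)


def eps_from_fluctuations(series: TrajectorySeries) -> tuple[float, float]:
    """Static dielectric constant from polarization fluctuations.

    Returns (eps_parallel, eps_perpendicular) where parallel refers to
    the field direction of the series and perpendicular averages the
    variance of the two transverse components.  The high-frequency
    dielectric constant is fixed at 1 (no electronic polarizability).
    """
    if series.n < 10:
        raise ValueError("need at least 10 samples to estimate a variance")
    norm = _fluct_norm(series)
    var = {lab: np.var(series.column(lab), ddof=1) for lab in series.labels}
    par = var.pop(series.field_direction)
    perp = np.mean(list(var.values()))
    return 1.0 + par / norm, 1.0 + perp / norm


def eps_diff_from_mean_polarization(series: TrajectorySeries) -> float:
    """Dielectric difference constant from the mean polarization at E0 > 0."""
    if series.applied_field <= 0:
        raise ValueError(
            "applied_field must be > 0; at zero field use eps_from_fluctuations")
    c = series.constants
    m = float(np.mean(series.column(series.field_direction)))
    return 1.0 + m / (c.eps0 * series.volume * series.applied_field)


def eps_slab_finite_difference(
    pair: SlabStatePair, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Differential dielectric constant from two slab states.

    eps = dD/(eps0 dE), assigned to the mean of the two midpoint fields.
    Symmetric under swapping the two states.
    """
    dE = pair.E_mid_high - pair.E_mid_low
    if dE == 0:
        raise ValueError("degenerate pair: the midpoint fields coincide")
    eps = (pair.D_high - pair.D_low) / (constants.eps0 * dE)
    E_assigned = 0.5 * (pair.E_mid_low + pair.E_mid_high)
    return eps, E_assigned


def autocorrelation(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Stationary autocovariance <x(0)x(tau)> for lags 0..n_lags.

    Biased estimator (1/n normalization at every lag), computed via FFT.
    The mean is *not* subtracted; callers pass mean-free series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: n_lags + 1]
    return acf / n


def viscosity_green_kubo(
    series: TrajectorySeries, component: str, tau_max: float
) -> float:
    """Shear viscosity from the Green--Kubo stress autocorrelation integral.

    eta = (V / kT) * mean over the component set of
          int_0^tau_max <P_ab(0) P_ab(tau)> dtau

    with the parallel set {xz, zx, xy, yx} and the perpendicular set
    {yz, zy} for a field along x.  Stress in bar, result in mPa s.
    """
    comp = str(component)
    if comp == "parallel":
        labels = PARALLEL_SET
    elif comp == "perpendicular":
        labels = PERPENDICULAR_SET
    else:
        raise ValueError(f"unknown component {component!r}")
    if tau_max > series.duration / 2:
        raise ValueError("tau_max must not exceed half the series duration")
    missing = [lab for lab in labels if lab not in series.labels]
    if missing:
        raise ValueError(f"series lacks stress components {missing}")

    n_lags = int(round(tau_max / series.dt))
    c = series.constants
    kT_J = c.kT_joule * series.temperature / c.temperature
    integrals = []
    for lab in labels:
        acf = autocorrelation(series.column(lab), n_lags)  # bar^2
        integrals.append(np.trapezoid(acf, dx=series.dt))  # bar^2 ps
    mean_integral = float(np.mean(integrals))
    return series.volume * mean_integral / kT_J * c.GREEN_KUBO_TO_MPAS
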