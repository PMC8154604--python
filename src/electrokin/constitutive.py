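"""Constitutive laws for the electrolyte dielectric constant and viscosity.

The static dielectric constant of an aqueous electrolyte decreases both
with salt concentration (dielectric decrement, Gavish--Promislow form)
and with electric field strength (dielectric saturation, Booth form).
The shear viscosity increases quadratically with salt concentration and
has an even, bounded-plus-quadratic dependence on field strength whose
sign differs between the tensor components parallel and perpendicular to
the field.  This module evaluates these laws in bulk, couples the two
dependencies through a multiplicative (default) or additive ansatz, and
extends them to interfacial profiles with an optional piecewise-constant
"box" layer of width ``z_int`` next to the wall.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "Combination",
    "Component",
    "ProfileMode",
    "DielectricModel",
    "ViscosityModel",
    "InterfaceSpec",
    "eps_salt",
    "eps_field_diff",
    "eps_combined",
    "eta_salt",
    "eta_field",
    "eta_combined",
    "eps_profile",
    "eta_profile",
]


class Combination(str, Enum):
    MULTIPLICATIVE = "multiplicative"
    ADDITIVE = "additive"


class Component(str, Enum):
    PARALLEL = "parallel"
    PERPENDICULAR = "perpendicular"


class ProfileMode(str, Enum):
    BULK_LIKE = "bulk_like"
    EXTENDED_BOX = "extended_box"


def _langevin(x):
    """Langevin function L(x) = coth(x) - 1/x, stable near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)  # dummy to avoid 0-division warnings
    out = np.where(small, x / 3.0 - x**3 / 45.0, 1.0 / np.tanh(xs) - 1.0 / xs)
    return out


def _langevin_over_x(x):
    """L(x)/x, even in x, -> 1/3 as x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 / 3.0 - x**2 / 45.0, _langevin(xs) / xs)


@dataclass(frozen=True)
class DielectricModel:
    """Parameters of the dielectric decrement and saturation laws.

    ``alpha`` (excess ionic polarizability, M^-1) and ``a_c`` are redundant;
    they are tied by a_c = 3 alpha / (eps_w - eps_ms) and only ``alpha`` is
    stored.  Salt decrement:

        eps(c) = eps_w + (eps_w - eps_ms) * L(a_c * c)

    which has eps(0) = eps_w, initial slope alpha and limit eps_ms.
    Field saturation of the *difference* constant (D = eps0*epsbar*E):

        epsbar(E) = eps_n + 3 (eps_w - eps_n) * L(a_E E)/(a_E E)

    with limits eps_w at E=0 and eps_n at infinite field.  The field/salt
    coupling is either multiplicative through the (eps - 1) excess,

        epsbar(E, c) = 1 + (epsbar(E) - 1)(eps(c) - 1)/(eps_w - 1)

    which preserves both marginals and never drops below 1, or plainly
    additive, epsbar(E) + eps(c) - eps_w, which can.
    """

    eps_w: float = 71.0
    eps_ms: float = 27.9
    alpha: float = -11.59  # M^-1
    eps_n: float = 4.0     # placeholder: no printed value exists
    a_E: float = 10.0      # nm/V, placeholder: no printed value exists
    combination: Combination = Combination.MULTIPLICATIVE

    def __post_init__(self) -> None:
        if not (self.eps_w > self.eps_ms >= 1.0):
            raise ValueError("require eps_w > eps_ms >= 1")
        if self.eps_n < 1.0:
            raise ValueError("require eps_n >= 1")
        if self.a_E <= 0:
            raise ValueError("require a_E > 0")

    @property
    def a_c(self) -> float:
        """Salt-dependence parameter, M^-1: a_c = 3 alpha/(eps_w - eps_ms)."""
        return 3.0 * self.alpha / (self.eps_w - self.eps_ms)

    @classmethod
    def from_a_c(cls, a_c: float, eps_w: float = 71.0, eps_ms: float = 27.9,
                 **kwargs) -> "DielectricModel":
        alpha = a_c * (eps_w - eps_ms) / 3.0
        return cls(eps_w=eps_w, eps_ms=eps_ms, alpha=alpha, **kwargs)


@dataclass(frozen=True)
class ViscosityModel:
    """Parameters of the electrolyte viscosity laws.

    Salt dependence is a second-degree polynomial
    eta(c) = eta_w + a_c1 c + a_c2 c^2.  Field dependence per tensor
    component is

        eta(E) = eta_w + a_E1 * (1 - 3 L(x)/x) + a_E2 * E^2,
        x = p0 E / k_B T

    whose first term is a bounded even series in E with the single
    prefactor a_E1 and whose final term gives the quadratic high-field
    growth.  The perpendicular component has a_E1 < 0 (initial decrease).
    """

    eta_w: float = 0.648       # mPa s
    a_c1: float = 0.0777       # mPa s / M
    a_c2: float = 0.0223       # mPa s / M^2
    a_E1_par: float = 0.160    # mPa s
    a_E2_par: float = 0.0868   # mPa s / (V/nm)^2
    a_E1_perp: float = -0.190  # mPa s
    a_E2_perp: float = 0.0319  # mPa s / (V/nm)^2
    p0: float = 0.049          # e nm (SPC/E water dipole moment)
    combination: Combination = Combination.MULTIPLICATIVE
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if self.eta_w <= 0:
            raise ValueError("require eta_w > 0")
        if self.p0 <= 0:
            raise ValueError("require p0 > 0")

    def field_coeffs(self, component: Component | str) -> tuple[float, float]:
        component = Component(component)
        if component is Component.PARALLEL:
            return self.a_E1_par, self.a_E2_par
        return self.a_E1_perp, self.a_E2_perp


@dataclass(frozen=True)
class InterfaceSpec:
    """Geometry, surface and interfacial-layer parameters of one interface.

    The defaults are the hydrophilic-surface set used throughout: steric
    ion diameter d = 0.3 nm, interfacial layer width z_int = 0.44 nm with
    dielectric constant 4.4 and viscosity 3.7 eta_w, Navier slip length
    b_s = -0.32 nm (a negative value models a stagnant layer), tangential
    driving field E_ext = 0.3 V/nm.
    """

    sigma0: float = 0.1        # e/nm^2, bare surface charge density
    c0: float = 0.01           # M, bulk salt concentration
    d: float = 0.3             # nm, steric ion diameter
    z_int: float = 0.44        # nm, interfacial layer width
    eps_int: float = 4.4       # dimensionless
    eta_int: float = 3.7 * 0.648  # mPa s
    b_s: float = -0.32         # nm, Navier slip length
    profile_mode: ProfileMode = ProfileMode.BULK_LIKE
    E_ext: float = 0.3         # V/nm, applied tangential field

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("require c0 > 0")
        if self.d < 0 or self.z_int < 0:
            raise ValueError("require d >= 0 and z_int >= 0")
        if self.eps_int < 1.0:
            raise ValueError("require eps_int >= 1")
        if self.eta_int <= 0:
            raise ValueError("require eta_int > 0")
        if self.E_ext <= 0:
            raise ValueError("require E_ext > 0")


# ---------------------------------------------------------------------------
# bulk laws


def eps_salt(c0, model: DielectricModel):
    """Zero-field dielectric constant vs salt concentration (decrement)."""
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0):
        raise ValueError("salt concentration must be non-negative")
    out = model.eps_w + (model.eps_w - model.eps_ms) * _langevin(model.a_c * c0)
    return out if out.ndim else float(out)


def eps_field_diff(E0, model: DielectricModel):
    """Zero-salt dielectric *difference* constant vs field (saturation).

    Even in the signed field; decreases from eps_w at E=0 to eps_n at
    infinite field.  The corresponding differential constant is
    d(E epsbar)/dE, and epsbar is its running field-average.
    """
    x = model.a_E * np.abs(np.asarray(E0, dtype=float))
    out = model.eps_n + 3.0 * (model.eps_w - model.eps_n) * _langevin_over_x(x)
    return out if out.ndim else float(out)


def eps_combined(E0, c0, model: DielectricModel):
    """Dielectric difference constant at finite field and concentration."""
    eb = np.asarray(eps_field_diff(E0, model), dtype=float)
    ec = np.asarray(eps_salt(c0, model), dtype=float)
    mode = Combination(model.combination)
    if mode is Combination.MULTIPLICATIVE:
        out = 1.0 + (eb - 1.0) * (ec - 1.0) / (model.eps_w - 1.0)
    else:
        out = eb + ec - model.eps_w
    out = np.asarray(out)
    return out if out.ndim else float(out)


def eta_salt(c0, model: ViscosityModel):
    """Zero-field viscosity vs salt concentration (quadratic polynomial)."""
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0):
        raise ValueError("salt concentration must be non-negative")
    out = model.eta_w + model.a_c1 * c0 + model.a_c2 * c0**2
    return out if out.ndim else float(out)


def eta_field(E0, component: Component | str, model: ViscosityModel):
    """Zero-salt viscosity vs field for one tensor component."""
    a1, a2 = model.field_coeffs(component)
    E0 = np.abs(np.asarray(E0, dtype=float))
    x = model.p0 * E0 / model.constants.kT_eV
    out = model.eta_w + a1 * (1.0 - 3.0 * _langevin_over_x(x)) + a2 * E0**2
    return out if out.ndim else float(out)


def eta_combined(E0, c0, component: Component | str, model: ViscosityModel):
    """Viscosity at finite field and concentration (one component)."""
    ef = np.asarray(eta_field(E0, component, model), dtype=float)
    ec = np.asarray(eta_salt(c0, model), dtype=float)
    mode = Combination(model.combination)
    if mode is Combination.MULTIPLICATIVE:
        out = ef * ec / model.eta_w
    else:
        out = ef + ec - model.eta_w
    out = np.asarray(out)
    if np.any(out <= 0):
        raise ValueError("viscosity model evaluated to a non-positive value "
                         "(outside supported domain)")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# interfacial profiles


def eps_profile(E, c, z, spec: InterfaceSpec, model: DielectricModel):
    """Local dielectric difference constant at height z above the wall.

    ``bulk_like`` applies the bulk law to the local field and
    concentration everywhere; ``extended_box`` overrides it with the
    constant eps_int inside the interfacial layer z < z_int.
    """
    bulk = np.asarray(eps_combined(E, c, model), dtype=float)
    if ProfileMode(spec.profile_mode) is ProfileMode.BULK_LIKE or spec.z_int == 0.0:
        return bulk if bulk.ndim else float(bulk)
    z = np.asarray(z, dtype=float)
    out = np.where(z < spec.z_int, spec.eps_int, bulk)
    return out if out.ndim else float(out)


def eta_profile(E, c, z, spec: InterfaceSpec, model: ViscosityModel):
    """Local viscosity at height z above the wall.

    The perpendicular tensor component is used: the double-layer field is
    normal to the wall and hence perpendicular to the tangential flow.
    """
    bulk = np.asarray(eta_combined(E, c, Component.PERPENDICULAR, model), dtype=float)
    if ProfileMode(spec.profile_mode) is ProfileMode.BULK_LIKE or spec.z_int == 0.0:
        return bulk if bulk.ndim else float(bulk)
    z = np.asarray(z, dtype=float)
    out = np.where(z < spec.z_int, spec.eta_int, bulk)
    return out if out.ndim else float(out)
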