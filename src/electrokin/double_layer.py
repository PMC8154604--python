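"""Modified Poisson--Boltzmann solver for a charged planar half-space.

Solves, on z in [0, z_max],

    d/dz [ eps0 * epsbar(E(z), c(z), z) * E(z) ] = rho(z),   E = -dpsi/dz

for a 1:1 electrolyte with Bikerman-type steric saturation of the ion
concentrations (fcc close packing at ion diameter d) and a local
dielectric difference constant that may depend on the local field, the
local mean salt concentration, and explicitly on z through an
interfacial box layer.  Boundary conditions: D(0+) = sigma0 (Gauss law,
no field behind the wall) and psi(z_max) = 0.

The nonlinearity in epsbar is handled by a damped fixed point: freeze
the epsbar profile, solve the resulting Poisson--Boltzmann problem by a
damped Newton iteration on a graded finite-volume grid, recompute
epsbar from the updated field and concentration profiles, relax, and
repeat until the potential stops moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .constitutive import DielectricModel, InterfaceSpec, eps_profile

__all__ = [
    "GridOptions",
    "DoubleLayerSolution",
    "steric_boltzmann",
    "debye_length",
    "grahame_sigma",
    "grahame_psi0",
    "solve_double_layer",
]


@dataclass(frozen=True)
class GridOptions:
    """Graded-grid and iteration controls for the half-space solver."""

    h_wall: float = 0.00025        # nm, first spacing at the wall
    growth: float = 1.01           # geometric growth factor
    z_max: float | None = None     # nm; default max(6, z_int + 12 lambda_D)
    outer_tol: float = 1e-8        # max |delta Psi| between outer iterations
    max_outer: int = 500
    newton_tol: float = 1e-9       # residual inf-norm (reduced units)
    max_newton: int = 100
    relax: float = 0.5             # damping of the epsbar update


@dataclass
class DoubleLayerSolution:
    """Converged profiles of the planar diffuse double layer.

    All arrays live on ``z_grid`` (nm, strictly increasing from 0).
    ``psi`` is the reduced potential e*psi/kT; ``E_field`` = -dpsi/dz in
    V/nm; concentrations in M; ``displacement`` = eps0*epsbar*E in
    e/nm^2; ``rho`` in e/nm^3.
    """

    z_grid: np.ndarray
    psi: np.ndarray
    E_field: np.ndarray
    c_plus: np.ndarray
    c_minus: np.ndarray
    eps_bar: np.ndarray
    displacement: np.ndarray
    rho: np.ndarray
    spec: InterfaceSpec
    converged: bool
    iterations: int
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    @property
    def c_mean(self) -> np.ndarray:
        """Local mean salt concentration (c+ + c-)/2 in M."""
        return 0.5 * (self.c_plus + self.c_minus)

    @property
    def psi0(self) -> float:
        """Reduced surface potential Psi(0)."""
        return float(self.psi[0])

    def net_charge(self) -> float:
        """Integrated fluid charge, e/nm^2; equals -sigma0 when neutral."""
        return float(np.trapezoid(self.rho, self.z_grid))


def steric_boltzmann(psi, c0: float, d: float):
    """Ion concentrations at reduced potential psi with steric saturation.

    Bikerman/Borukhov form with the fcc close-packing ceiling
    c_max = sqrt(2)/d^3 (converted to molar):

        c_pm = c0 exp(-/+ psi) / (1 + (2 c0/c_max)(cosh psi - 1))

    d = 0 recovers ideal Boltzmann factors; c_+ + c_- never exceeds c_max.
    Returns (c_plus, c_minus) in M.
    """
    if d < 0:
        raise ValueError("steric diameter must be non-negative")
    psi = np.asarray(psi, dtype=float)
    if d == 0.0:
        return c0 * np.exp(-psi), c0 * np.exp(psi)
    c_max = np.sqrt(2.0) / d**3 / DEFAULT_CONSTANTS.avogadro_factor  # M
    # work with exp(-|psi|) to avoid overflow at large |psi|
    a = np.abs(psi)
    em = np.exp(-a)                    # <= 1
    # denominator scaled by exp(-a): em + (c0/c_max)(1 - em)^2, since
    # 2(cosh a - 1) e^{-a} = (1 - e^{-a})^2
    den_scaled = em + (c0 / c_max) * (1.0 - em) ** 2
    c_counter = c0 / den_scaled            # Boltzmann factor e^{+a}
    c_co = c0 * em**2 / den_scaled         # Boltzmann factor e^{-a}
    c_plus = np.where(psi >= 0, c_co, c_counter)
    c_minus = np.where(psi >= 0, c_counter, c_co)
    return (c_plus if c_plus.ndim else float(c_plus),
            c_minus if c_minus.ndim else float(c_minus))


def debye_length(c0: float, eps: float,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Debye screening length in nm for a 1:1 electrolyte at c0 molar."""
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    n0 = c0 * constants.avogadro_factor  # nm^-3
    return float(np.sqrt(constants.eps0 * eps * constants.thermal_voltage
                         / (2.0 * n0)))


def grahame_sigma(zeta_reduced, c0: float, eps: float,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Grahame equation: surface charge density (e/nm^2) at reduced potential.

    sigma = 2 eps0 eps kappa (kT/e) sinh(Psi/2), monovalent ions.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    kappa = 1.0 / debye_length(c0, eps, constants)
    pref = 2.0 * constants.eps0 * eps * kappa * constants.thermal_voltage
    out = pref * np.sinh(np.asarray(zeta_reduced, dtype=float) / 2.0)
    return out if out.ndim else float(out)


def grahame_psi0(sigma0: float, c0: float, eps: float,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse Grahame relation: reduced surface potential at given sigma0."""
    kappa = 1.0 / debye_length(c0, eps, constants)
    pref = 2.0 * constants.eps0 * eps * kappa * constants.thermal_voltage
    return float(2.0 * np.arcsinh(sigma0 / pref))


class DoubleLayerError(RuntimeError):
    """Raised when the modified PB solver fails to converge."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


def _graded_grid(spec: InterfaceSpec, model: DielectricModel,
                 opts: GridOptions) -> np.ndarray:
    z_max = opts.z_max
    if z_max is None:
        lam = debye_length(spec.c0, model.eps_w)
        z_max = max(6.0, spec.z_int + 12.0 * lam)
    z = [0.0]
    h = opts.h_wall
    while z[-1] < z_max:
        z.append(z[-1] + h)
        h *= opts.growth
    z[-1] = z_max
    return np.asarray(z)


def _rho_reduced(psi, c0, d, constants):
    """Charge density rho/(eps0 * kT/e), units 1/nm^2, and its psi-derivative."""
    # clip: converged potentials stay below ~50, but Newton intermediates can
    # overshoot into exp-overflow territory in the ideal (d = 0) branch
    psi = np.clip(np.asarray(psi, dtype=float), -300.0, 300.0)
    cp, cm = steric_boltzmann(psi, c0, d)
    rho = (np.asarray(cp) - np.asarray(cm)) * constants.avogadro_factor  # e/nm^3
    scale = 1.0 / (constants.eps0 * constants.thermal_voltage)
    # derivative by small central difference (analytic form is unwieldy with
    # the steric denominator; the step is far below solver tolerance impact)
    h = 1e-6
    cp2, cm2 = steric_boltzmann(psi + h, c0, d)
    cp1, cm1 = steric_boltzmann(psi - h, c0, d)
    drho = ((np.asarray(cp2) - np.asarray(cm2))
            - (np.asarray(cp1) - np.asarray(cm1))) * constants.avogadro_factor / (2 * h)
    return rho * scale, drho * scale


def _solve_pb_fixed_eps(z, eps_face, psi, sigma0_red, c0, d, constants, opts):
    """Damped Newton for the PB problem with a frozen epsbar face profile.

    z: nodes (N+1,), eps_face: epsbar at the N cell faces, psi: initial
    guess, sigma0_red = sigma0/(eps0 kT/e) in 1/nm.  Returns converged psi.
    """
    n = z.size
    h = np.diff(z)                         # (n-1,) face spacings
    w = np.empty(n)                        # control-volume widths
    w[0] = h[0] / 2
    w[-1] = h[-1] / 2
    w[1:-1] = (h[:-1] + h[1:]) / 2
    cond = eps_face / h                    # face conductances

    def residual_and_diag(p):
        rho_red, drho_red = _rho_reduced(p, c0, d, constants)
        F = np.zeros(n)
        flux = cond * (p[1:] - p[:-1])     # eps * dpsi/dz at faces
        F[0] = flux[0] + sigma0_red + rho_red[0] * w[0]
        F[1:-1] = flux[1:] - flux[:-1] + rho_red[1:-1] * w[1:-1]
        F[-1] = p[-1]                      # Dirichlet psi(z_max) = 0
        diag = np.empty(n)
        diag[0] = -cond[0] + drho_red[0] * w[0]
        diag[1:-1] = -(cond[1:] + cond[:-1]) + drho_red[1:-1] * w[1:-1]
        diag[-1] = 1.0
        return F, diag

    history = []
    for _ in range(opts.max_newton):
        F, diag = residual_and_diag(psi)
        res = float(np.max(np.abs(F)))
        history.append(res)
        if res < opts.newton_tol:
            return psi
        # tridiagonal Jacobian in banded storage
        ab = np.zeros((3, n))
        ab[0, 1:] = cond                   # superdiagonal J[i, i+1]
        ab[0, -1] = 0.0                    # last row is Dirichlet
        ab[1, :] = diag
        ab[2, :-1] = cond                  # subdiagonal J[i+1, i]
        ab[2, -2] = 0.0
        step = solve_banded((1, 1), ab, -F)
        if np.max(np.abs(step)) < 1e-13:   # at the floating-point floor
            return psi
        # backtracking line search on the residual norm
        t = 1.0
        for _ in range(60):
            F_new, _ = residual_and_diag(psi + t * step)
            if np.max(np.abs(F_new)) < res:
                break
            t /= 2.0
        else:
            if res < 1e-6:                 # rounding floor, solution is fine
                return psi
            raise DoubleLayerError(
                "Newton line search stalled", residual_history=history)
        psi = psi + t * step
    raise DoubleLayerError(
        f"PB Newton did not reach tolerance (last residual {history[-1]:.3e})",
        residual_history=history)


def solve_double_layer(
    spec: InterfaceSpec,
    dielectric: DielectricModel,
    grid: GridOptions | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DoubleLayerSolution:
    """Solve the modified PB problem for one charged planar interface."""
    opts = grid or GridOptions()
    z = _graded_grid(spec, dielectric, opts)
    n = z.size
    z_face = 0.5 * (z[:-1] + z[1:])

    psi = np.zeros(n)
    sigma0_red = spec.sigma0 / (constants.eps0 * constants.thermal_voltage)

    # initial epsbar: zero-field bulk value everywhere (box applied on top)
    eps_nodes = np.asarray(
        eps_profile(0.0, np.full(n, spec.c0), z, spec, dielectric), dtype=float)
    eps_nodes = np.broadcast_to(eps_nodes, (n,)).copy()

    outer_iter = 0
    converged = False
    for outer_iter in range(1, opts.max_outer + 1):
        eps_face = 0.5 * (eps_nodes[:-1] + eps_nodes[1:])
        psi_new = _solve_pb_fixed_eps(
            z, eps_face, psi.copy(), sigma0_red, spec.c0, spec.d, constants, opts)
        dpsi = float(np.max(np.abs(psi_new - psi)))
        psi = psi_new
        # update epsbar from the new field and concentration profiles
        E = -constants.thermal_voltage * np.gradient(psi, z)  # V/nm
        cp, cm = steric_boltzmann(psi, spec.c0, spec.d)
        c_mean = 0.5 * (np.asarray(cp) + np.asarray(cm))
        eps_target = np.asarray(
            eps_profile(np.abs(E), c_mean, z, spec, dielectric), dtype=float)
        eps_target = np.broadcast_to(eps_target, (n,))
        max_deps = float(np.max(np.abs(eps_target - eps_nodes)))
        eps_nodes = (1 - opts.relax) * eps_nodes + opts.relax * eps_target
        if dpsi < opts.outer_tol and max_deps < 1e-8:
            converged = True
            break
    if not converged:
        raise DoubleLayerError(
            f"outer epsbar loop did not converge in {opts.max_outer} iterations")

    i_check = int(np.searchsorted(z, 0.9 * z[-1]))
    if abs(psi[i_check]) > 1e-4 * max(1.0, abs(psi[0])):
        raise DoubleLayerError(
            "domain truncation too aggressive: potential has not decayed "
            "at 0.9 z_max; enlarge GridOptions.z_max")

    E = -constants.thermal_voltage * np.gradient(psi, z)
    cp, cm = steric_boltzmann(psi, spec.c0, spec.d)
    cp = np.asarray(cp, dtype=float)
    cm = np.asarray(cm, dtype=float)
    rho = (cp - cm) * constants.avogadro_factor
    D = constants.eps0 * eps_nodes * E
    return DoubleLayerSolution(
        z_grid=z, psi=psi, E_field=E, c_plus=cp, c_minus=cm,
        eps_bar=eps_nodes, displacement=D, rho=rho, spec=spec,
        converged=True, iterations=outer_iter, constants=constants)
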