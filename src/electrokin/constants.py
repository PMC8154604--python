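"""Physical constants in the package unit system.

The whole package works in one fixed unit system chosen so that numbers
stay of order unity for nanoscale double layers:

=============  =========================
quantity       unit
=============  =========================
length         nm
electric field V/nm
charge         e (elementary charge)
concentration  M (mol/L)
viscosity      mPa s
surface charge e/nm^2
time           ps (trajectories), ns (flow velocities)
=============  =========================
"""

from __future__ import annotations

from dataclasses import dataclass

#: elementary charge in coulomb, used only inside unit-conversion factors
_E_COULOMB = 1.602176634e-19

#: Boltzmann constant in J/K
_KB_JOULE = 1.380649e-23


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the fixed package unit system at a given temperature.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin.
    thermal_voltage : float
        k_B T / e in volts (0.025852 V at 300 K).
    eps0 : float
        Vacuum permittivity in e / (V nm).
    avogadro_factor : float
        Number density per molar concentration, nm^-3 / M.
    """

    temperature: float = 300.0
    thermal_voltage: float = 0.025852
    eps0: float = 8.8541878128e-12 / _E_COULOMB * 1e-9  # e / (V nm)
    avogadro_factor: float = 6.02214076e23 * 1e-24  # nm^-3 per M

    def __post_init__(self) -> None:
        for name in ("temperature", "thermal_voltage", "eps0", "avogadro_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT_eV(self) -> float:
        """Thermal energy in e*V (numerically equal to thermal_voltage)."""
        return self.thermal_voltage

    @property
    def kT_joule(self) -> float:
        """Thermal energy in joule, for stress-unit conversions."""
        return self.thermal_voltage * _E_COULOMB

    # --- centralized unit conversions -------------------------------------

    #: multiply (e V / (nm^2 mPa s)) by this to obtain nm/ns;
    #: 1 e V/(nm^2 mPa s) = 1.602e-19 J/(1e-18 m^2 * 1e-3 Pa s) = 160.2 m/s
    #: and 1 m/s = 1 nm/ns exactly
    VELOCITY_TO_NM_PER_NS: float = _E_COULOMB / 1e-21

    #: multiply (bar^2 ps nm^3 / J) by this to obtain mPa s
    GREEN_KUBO_TO_MPAS: float = 1e10 * 1e-12 * 1e-27 * 1e3

DEFAULT_CONSTANTS = PhysicalConstants()
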