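"""Physical constants and the package-wide unit contract.

Internal units are Angstrom (length), dalton (mass), millielectronvolt
(energy), elementary charge (charge) and picosecond (time).  All conversions
between these and SI happen here; no other module hard-codes a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "KB_MEV",
    "COULOMB_MEV_A",
    "MEV_TO_DA_A2_PS2",
    "STANDARD_TEMPERATURE_K",
    "STANDARD_PRESSURE_PA",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values in SI units; frozen so they cannot drift at run time.

    Attributes
    ----------
    k_B : float
        Boltzmann constant, J/K.
    e_charge : float
        Elementary charge, C.
    amu : float
        Atomic mass unit, kg.
    loschmidt : float
        Number density of an ideal gas at 273.15 K and 101325 Pa, m^-3.
    """

    k_B: float = 1.380649e-23
    e_charge: float = 1.602176634e-19
    amu: float = 1.66053906660e-27
    loschmidt: float = 2.686780111e25


CONSTANTS = PhysicalConstants()

#: Boltzmann constant in meV/K.
KB_MEV = CONSTANTS.k_B / CONSTANTS.e_charge * 1e3 / 1.0  # 8.617333e-2

#: Coulomb energy of two unit charges 1 Angstrom apart, in meV
#: (e^2 / (4 pi eps0 * 1 A)).
COULOMB_MEV_A = 14399.645478425668

#: 1 meV expressed in Da * A^2 / ps^2 (kinetic-energy unit of the integrator).
MEV_TO_DA_A2_PS2 = CONSTANTS.e_charge * 1e-3 / (CONSTANTS.amu * 1e-20 / 1e-24)

STANDARD_TEMPERATURE_K = 273.15
STANDARD_PRESSURE_PA = 101325.0
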