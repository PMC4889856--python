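"""Mobility conversions: cross section -> K (Mason-Schamp), drift time -> K,
and the nitrogen -> oxygen/air corrections.

Low-field regime throughout.  The Mason-Schamp relation

    K = (3/16) (q/N) sqrt(2 pi / (mu kB T)) / Omega,   mu = m M / (m + M)

converts a momentum-transfer cross section Omega to a mobility; measured
drift times convert through K = L^2 / (t_D U).  Mobilities computed for N2
are transferred to O2 via the Langevin polarization-limit ratio
(K proportional to 1/sqrt(alpha mu), with the gas polarizability alpha
proportional to D - 1 for dielectric constant D) and then to air by Blanc's
law with the 0.79/0.21 N2/O2 molar composition.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .constants import (
    CONSTANTS,
    STANDARD_PRESSURE_PA,
    STANDARD_TEMPERATURE_K,
)

__all__ = [
    "Conditions",
    "InstrumentGeometry",
    "GasProperties",
    "MobilityValue",
    "MeasuredPeak",
    "standard_number_density",
    "gas_properties",
    "mason_schamp",
    "mobility_from_drift",
    "o2_from_n2",
    "blanc_mix",
    "air_from_n2",
    "AIR_COMPOSITION",
]

#: molar composition used for "air" (argon folded into N2)
AIR_COMPOSITION = (("N2", 0.79), ("O2", 0.21))


def standard_number_density(T: float = STANDARD_TEMPERATURE_K,
                            p: float = STANDARD_PRESSURE_PA) -> float:
    """Ideal-gas number density in cm^-3 at *T* (K) and *p* (Pa)."""
    return p / (CONSTANTS.k_B * T) * 1e-6


@dataclass(frozen=True)
class Conditions:
    """Temperature (K), drift-gas number density (cm^-3) and composition."""

    temperature: float
    number_density: float
    composition: tuple[tuple[str, float], ...] = (("N2", 1.0),)

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.number_density <= 0:
            raise ValueError("temperature and number density must be positive")
        total = sum(x for _, x in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class InstrumentGeometry:
    """Drift length L (cm) and total voltage drop U (V) of the drift tube."""

    length: float
    voltage: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.voltage <= 0:
            raise ValueError("drift length and voltage must be positive")


@dataclass(frozen=True)
class GasProperties:
    """Molecular mass (Da) and dielectric constant of a drift gas."""

    name: str
    mass: float
    dielectric: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("gas mass must be positive")
        if self.dielectric <= 1.0:
            raise ValueError("dielectric constant must exceed 1")


@functools.lru_cache(maxsize=None)
def _gas_table() -> dict[str, GasProperties]:
    with resources.files("iontraj.data").joinpath("gas_properties.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return {
        row["name"]: GasProperties(row["name"], row["mass_da"], row["dielectric"])
        for _, row in df.iterrows()
    }


def gas_properties(name: str) -> GasProperties:
    """Packaged gas constants (CRC-style values at 20 C, 1 atm)."""
    table = _gas_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"no packaged properties for gas {name!r}") from None


@dataclass(frozen=True)
class MobilityValue:
    """A mobility K (cm^2 V^-1 s^-1) plus the reduced mobility K0 and the
    conditions it refers to."""

    K: float
    K0: float
    conditions: Conditions

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("mobility must be positive")


@dataclass(frozen=True)
class MeasuredPeak:
    """A drift-time peak: t_D in ms, intensity in arbitrary units."""

    drift_time: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.drift_time <= 0:
            raise ValueError("drift time must be positive")


def _reduce_to_standard(K: float, conditions: Conditions) -> float:
    """K0 = K * N / N0 with N0 the standard-condition number density."""
    return K * conditions.number_density / standard_number_density()


def mason_schamp(
    omega: float,
    m: float,
    M: float,
    q: int = 1,
    T: float = 298.15,
    N: float | None = None,
    composition: tuple[tuple[str, float], ...] = (("N2", 1.0),),
) -> MobilityValue:
    """Mobility from a cross section via the Mason-Schamp equation.

    Parameters: ``omega`` in A^2; analyte and gas masses ``m``, ``M`` in Da;
    charge ``q`` in units of e; ``N`` in cm^-3 (defaults to the ideal-gas
    density at *T* and 1 atm).
    """
    if N is None:
        N = standard_number_density(T)
    if min(omega, m, M, q, T, N) <= 0:
        raise ValueError("all Mason-Schamp inputs must be positive")
    mu_kg = (m * M / (m + M)) * CONSTANTS.amu
    k_si = (
        (3.0 / 16.0)
        * (q * CONSTANTS.e_charge / (N * 1e6))
        * np.sqrt(2.0 * np.pi / (mu_kg * CONSTANTS.k_B * T))
        / (omega * 1e-20)
    )  # m^2 V^-1 s^-1
    K = k_si * 1e4
    cond = Conditions(temperature=T, number_density=N, composition=tuple(composition))
    return MobilityValue(K=K, K0=_reduce_to_standard(K, cond), conditions=cond)


def mobility_from_drift(
    geom: InstrumentGeometry,
    peak: MeasuredPeak,
    conditions: Conditions | None = None,
) -> MobilityValue:
    """K = L^2 / (t_D U) from a measured drift time."""
    t_s = peak.drift_time * 1e-3
    K = geom.length**2 / (t_s * geom.voltage)
    cond = conditions or Conditions(298.15, standard_number_density(298.15))
    return MobilityValue(K=K, K0=_reduce_to_standard(K, cond), conditions=cond)


def langevin_ratio(m: float, n2: GasProperties, o2: GasProperties) -> float:
    """K_O2 / K_N2 in the polarization limit for analyte mass *m* (Da)."""
    if m <= 0:
        raise ValueError("analyte mass must be positive")
    num = (n2.dielectric - 1.0) * n2.mass * (m + o2.mass)
    den = (o2.dielectric - 1.0) * o2.mass * (m + n2.mass)
    return float(np.sqrt(num / den))


def o2_from_n2(
    K_n2: MobilityValue,
    m: float,
    props: tuple[GasProperties, GasProperties] | None = None,
) -> MobilityValue:
    """Transfer a nitrogen mobility to oxygen via the Langevin limit.

    K depends on gas only through 1/sqrt(alpha mu) in this limit; with
    alpha proportional to (D - 1) the ratio needs just the two dielectric
    constants and masses.
    """
    n2, o2 = props if props is not None else (gas_properties("N2"), gas_properties("O2"))
    ratio = langevin_ratio(m, n2, o2)
    cond = replace(K_n2.conditions, composition=(("O2", 1.0),))
    K = K_n2.K * ratio
    return MobilityValue(K=K, K0=_reduce_to_standard(K, cond), conditions=cond)


def blanc_mix(values: list[tuple[MobilityValue, float]]) -> MobilityValue:
    """Blanc's law: 1/K_mix = sum_i x_i / K_i for mole fractions x_i."""
    if not values:
        raise ValueError("need at least one component")
    total = sum(x for _, x in values)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mole fractions must sum to 1, got {total}")
    inv = sum(x / mv.K for mv, x in values)
    K = 1.0 / inv
    base = values[0][0].conditions
    comp = []
    for mv, x in values:
        comp.extend((g, x * f) for g, f in mv.conditions.composition)
    cond = replace(base, composition=tuple(comp))
    return MobilityValue(K=K, K0=_reduce_to_standard(K, cond), conditions=cond)


def air_from_n2(
    K_n2: MobilityValue,
    m: float,
    composition: tuple[tuple[str, float], ...] = AIR_COMPOSITION,
) -> MobilityValue:
    """Nitrogen mobility -> air mobility (Langevin O2 ratio + Blanc's law)."""
    parts = []
    for gas, x in composition:
        if gas == "N2":
            parts.append((K_n2, x))
        elif gas == "O2":
            parts.append((o2_from_n2(K_n2, m), x))
        else:
            raise KeyError(f"no transfer rule for gas {gas!r}")
    return blanc_mix(parts)
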