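"""Ion / drift-gas interaction: Lennard-Jones sites, gas point charges
(N2 quadrupole) and the charge-induced-dipole term.

The functional form follows the nitrogen-extended trajectory-method
lineage: each ion atom interacts with the gas LJ site(s) through a 12-6
potential with per-element parameters, the ion's partial charges interact
with the gas point-charge model of the N2 quadrupole, and the gas is
polarized by the electric field of the partial charges at its center of
mass, contributing -(alpha/2)|E|^2.

Two nitrogen models are provided:

``N2``
    two LJ sites 1.10 A apart plus three point charges
    (-0.4825, +0.965, -0.4825 e) reproducing the molecular quadrupole.
``N2-iso``
    a single isotropic LJ site, no quadrupole; considerably cheaper and the
    default for desk-scale runs.

The per-element LJ well depths/diameters are an informed default in the
published MOBCAL-for-N2 lineage (H, C, N, O); they are echoed into result
metadata and can be overridden from a YAML config keyed by element symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from ._kernels import eval_potential_force
from .constants import COULOMB_MEV_A
from .structures import MolecularIon

__all__ = [
    "LJParameters",
    "GasSite",
    "DriftGasModel",
    "drift_gas",
    "NearSingularityError",
    "potential_energy",
    "force",
    "DEFAULT_LJ_TABLE",
    "R_MIN_GUARD",
]

#: atom-site distance below which the potential is considered singular, A
R_MIN_GUARD = 0.2

#: per-element (epsilon meV, sigma A) versus molecular nitrogen
DEFAULT_LJ_TABLE: dict[str, tuple[float, float]] = {
    "H": (0.82, 2.38),
    "C": (4.65, 3.50),
    "N": (4.55, 3.38),
    "O": (4.39, 3.04),
}


class NearSingularityError(ArithmeticError):
    """Probe came closer than the guard radius to an ion atom."""


@dataclass(frozen=True)
class LJParameters:
    """Per-element Lennard-Jones parameters for ion-atom / gas-site pairs.

    Stored directly per pair (no combining rule), the way trajectory-method
    parameter tables are published.  ``epsilon`` in meV, ``sigma`` in A.
    """

    epsilon: Mapping[str, float]
    sigma: Mapping[str, float]
    combining_rule: str = "explicit-pair"

    @classmethod
    def default(cls) -> "LJParameters":
        return cls(
            epsilon={k: v[0] for k, v in DEFAULT_LJ_TABLE.items()},
            sigma={k: v[1] for k, v in DEFAULT_LJ_TABLE.items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LJParameters":
        """Load ``{element: {epsilon: meV, sigma: A}}`` from a YAML file."""
        raw = yaml.safe_load(Path(path).read_text())
        eps = {el: float(d["epsilon"]) for el, d in raw.items()}
        sig = {el: float(d["sigma"]) for el, d in raw.items()}
        return cls(epsilon=eps, sigma=sig)

    def for_ion(self, ion: MolecularIon) -> tuple[np.ndarray, np.ndarray]:
        """(epsilon, sigma) arrays aligned with the ion's atom order."""
        eps = np.empty(len(ion))
        sig = np.empty(len(ion))
        for i, el in enumerate(ion.elements):
            if el not in self.epsilon or el not in self.sigma:
                raise KeyError(
                    f"no Lennard-Jones parameters tabulated for element {el!r}; "
                    "provide them via an LJParameters override"
                )
            if self.epsilon[el] <= 0 or self.sigma[el] <= 0:
                raise ValueError(f"LJ parameters for {el!r} must be positive")
            eps[i] = self.epsilon[el]
            sig[i] = self.sigma[el]
        return eps, sig


@dataclass(frozen=True)
class GasSite:
    """One interaction site of the gas, at ``offset`` A along the gas axis."""

    offset: float
    lennard_jones: bool
    charge: float = 0.0


@dataclass(frozen=True)
class DriftGasModel:
    """The collision partner: mass, polarizability and interaction sites."""

    name: str
    mass: float  # Da
    polarizability: float  # A^3
    sites: tuple[GasSite, ...]
    quadrupole: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.polarizability <= 0:
            raise ValueError("gas mass and polarizability must be positive")
        qsum = sum(s.charge for s in self.sites)
        if abs(qsum) > 1e-12:
            raise ValueError(f"gas point charges must sum to 0, got {qsum:+.3e} e")

    @property
    def site_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        off = np.array([s.offset for s in self.sites])
        lj = np.array([1 if s.lennard_jones else 0 for s in self.sites], dtype=np.int64)
        q = np.array([s.charge for s in self.sites])
        return off, lj, q

    @property
    def multi_site(self) -> bool:
        return len(self.sites) > 1


_N2_BOND = 1.10  # N-N distance, A
_N2_ALPHA = 1.710  # A^3
_N2_QCHARGE = 0.4825  # magnitude of the N-site partial charges, e

_GASES = {
    "N2": DriftGasModel(
        name="N2",
        mass=28.0134,
        polarizability=_N2_ALPHA,
        sites=(
            GasSite(-_N2_BOND / 2, True, -_N2_QCHARGE),
            GasSite(0.0, False, 2 * _N2_QCHARGE),
            GasSite(+_N2_BOND / 2, True, -_N2_QCHARGE),
        ),
        quadrupole=True,
    ),
    "N2-iso": DriftGasModel(
        name="N2-iso",
        mass=28.0134,
        polarizability=_N2_ALPHA,
        sites=(GasSite(0.0, True, 0.0),),
        quadrupole=False,
    ),
}


def drift_gas(name: str) -> DriftGasModel:
    """Look up a packaged drift-gas model (``"N2"`` or ``"N2-iso"``)."""
    try:
        return _GASES[name]
    except KeyError:
        raise KeyError(
            f"unknown drift gas {name!r}; available: {sorted(_GASES)}"
        ) from None


_Z_AXIS = np.array([0.0, 0.0, 1.0])


def _evaluate(
    ion: MolecularIon,
    gas: DriftGasModel,
    gas_center: np.ndarray,
    gas_axis: np.ndarray | None,
    lj: LJParameters,
    rmin_guard: float,
):
    center = np.asarray(gas_center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("gas_center must be finite")
    if gas_axis is None:
        axis = _Z_AXIS
    else:
        axis = np.asarray(gas_axis, dtype=float)
        if gas.multi_site and abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("gas_axis must be a unit vector for multi-site gases")
    eps, sig = lj.for_ion(ion)
    off, ljf, sq = gas.site_arrays
    V, F, tau, ok = eval_potential_force(
        center,
        axis,
        ion.positions,
        ion.partial_charges,
        eps,
        sig,
        off,
        ljf,
        sq,
        gas.polarizability,
        COULOMB_MEV_A,
        rmin_guard,
    )
    if not ok:
        raise NearSingularityError(
            f"probe within {rmin_guard} A of an ion atom at {center}"
        )
    return V, F, tau


def potential_energy(
    ion: MolecularIon,
    gas: DriftGasModel,
    gas_center,
    gas_axis=None,
    lj: LJParameters | None = None,
    rmin_guard: float = R_MIN_GUARD,
) -> float:
    """Interaction energy in meV of the gas probe at *gas_center*."""
    lj = lj or LJParameters.default()
    V, _, _ = _evaluate(ion, gas, gas_center, gas_axis, lj, rmin_guard)
    return float(V)


def force(
    ion: MolecularIon,
    gas: DriftGasModel,
    gas_center,
    gas_axis=None,
    lj: LJParameters | None = None,
    rmin_guard: float = R_MIN_GUARD,
    return_torque: bool = False,
):
    """Force on the probe center, -grad V, in meV/A (analytic).

    With ``return_torque=True`` also returns the torque (meV) about the gas
    center for multi-site gases; the orientation itself is frozen during
    trajectories, so the torque is diagnostic only.
    """
    lj = lj or LJParameters.default()
    _, F, tau = _evaluate(ion, gas, gas_center, gas_axis, lj, rmin_guard)
    if return_torque:
        return np.asarray(F), np.asarray(tau)
    return np.asarray(F)
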