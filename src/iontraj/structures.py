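"""Charged molecular geometries: domain types, file I/O and rigid motions.

The on-disk format is an XYZ dialect with a fifth per-atom column holding the
partial charge in units of e, and ``charge=<int>`` in the comment line::

    4
    hydronium charge=1
    O   0.000000   0.000000   0.000000  -0.400000
    H   0.923661   0.000000  -0.326875   0.466667
    ...

Files without the charge column are rejected: the partial-charge distribution
is an essential input of the trajectory method, not an optional annotation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularIon",
    "XYZQParseError",
    "ChargeSumError",
    "atomic_mass",
    "read_xyzq",
    "write_xyzq",
    "write_mobcal_input",
    "rigid_transform",
]

#: tolerance on |sum of partial charges - declared total charge|, in e
DEFAULT_CHARGE_TOLERANCE = 0.01


class XYZQParseError(ValueError):
    """Raised when an xyzq file is malformed; message names the line."""


class ChargeSumError(ValueError):
    """Raised when the partial charges do not add up to the total charge."""


@functools.lru_cache(maxsize=None)
def atomic_mass(element: str) -> float:
    """Standard atomic weight of *element* in Da.

    Raises ``ValueError`` for symbols without a tabulated mass.
    """
    from rdkit.Chem import GetPeriodicTable  # deferred: rdkit import is slow

    table = GetPeriodicTable()
    try:
        mass = table.GetAtomicWeight(element)
    except Exception as exc:  # rdkit raises a RuntimeError on bad symbols
        raise ValueError(f"unknown element symbol {element!r}") from exc
    if mass <= 0:
        raise ValueError(f"element {element!r} has no tabulated mass")
    return float(mass)


@dataclass(frozen=True)
class Atom:
    """One atom of a molecular ion.

    ``position`` is Cartesian in Angstrom, ``partial_charge`` in units of e.
    ``mass`` defaults to the standard atomic weight of ``element``.
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    mass: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        object.__setattr__(self, "position", pos)
        if self.mass is None:
            object.__setattr__(self, "mass", atomic_mass(self.element))
        elif self.mass <= 0:
            raise ValueError("atomic mass must be positive")


@dataclass(frozen=True)
class MolecularIon:
    """A rigid molecular ion: ordered atoms plus an integer total charge."""

    name: str
    atoms: tuple[Atom, ...]
    total_charge: int = 1
    charge_tolerance: float = DEFAULT_CHARGE_TOLERANCE

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        if not atoms:
            raise ValueError("a MolecularIon needs at least one atom")
        object.__setattr__(self, "atoms", atoms)
        qsum = sum(a.partial_charge for a in atoms)
        if abs(qsum - self.total_charge) > self.charge_tolerance:
            raise ChargeSumError(
                f"partial charges of {self.name!r} sum to {qsum:+.4f} e but the "
                f"declared total charge is {self.total_charge:+d} e "
                f"(tolerance {self.charge_tolerance} e)"
            )

    # -- array views ---------------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in Angstrom."""
        return np.array([a.position for a in self.atoms])

    @property
    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def mass(self) -> float:
        """Molecular mass in Da (sum of atomic masses)."""
        return float(self.masses.sum())

    @property
    def nominal_mass(self) -> int:
        """Integer-rounded molecular mass, as quoted for IMS species."""
        return int(round(self.mass))

    def __len__(self) -> int:
        return len(self.atoms)


def _make_ion(
    name: str,
    elements: Sequence[str],
    positions: np.ndarray,
    charges: Sequence[float],
    total_charge: int,
    charge_tolerance: float = DEFAULT_CHARGE_TOLERANCE,
) -> MolecularIon:
    atoms = tuple(
        Atom(el, np.asarray(pos, dtype=float), float(q))
        for el, pos, q in zip(elements, positions, charges, strict=True)
    )
    return MolecularIon(name, atoms, total_charge, charge_tolerance)


# -- file I/O ----------------------------------------------------------------


def read_xyzq(
    path: str | Path, charge_tolerance: float = DEFAULT_CHARGE_TOLERANCE
) -> MolecularIon:
    """Read a molecular ion from an xyzq file (XYZ + per-atom charge column)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise XYZQParseError(f"{path}: fewer than two header lines")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZQParseError(f"{path}, line 1: expected an atom count") from exc
    comment = lines[1]
    total_charge = 0
    for token in comment.split():
        if token.startswith("charge="):
            try:
                total_charge = int(token[len("charge="):])
            except ValueError as exc:
                raise XYZQParseError(
                    f"{path}, line 2: malformed charge token {token!r}"
                ) from exc
            break
    name = comment.split("charge=")[0].strip() or path.stem
    if len(lines) < 2 + n_atoms:
        raise XYZQParseError(
            f"{path}: header declares {n_atoms} atoms but only "
            f"{len(lines) - 2} atom lines follow"
        )
    elements, positions, charges = [], [], []
    for i, line in enumerate(lines[2 : 2 + n_atoms], start=3):
        parts = line.split()
        if len(parts) != 5:
            raise XYZQParseError(
                f"{path}, line {i}: expected 'element x y z charge', got {line!r}"
            )
        try:
            xyz = [float(p) for p in parts[1:4]]
            q = float(parts[4])
        except ValueError as exc:
            raise XYZQParseError(f"{path}, line {i}: non-numeric field") from exc
        elements.append(parts[0])
        positions.append(xyz)
        charges.append(q)
    return _make_ion(
        name, elements, np.array(positions), charges, total_charge, charge_tolerance
    )


def write_xyzq(ion: MolecularIon, path: str | Path) -> None:
    """Write *ion* in the xyzq dialect, re-readable by :func:`read_xyzq`.

    Coordinates and charges are written with six decimals, which preserves
    the 1e-6 A round-trip contract.
    """
    path = Path(path)
    out = [str(len(ion)), f"{ion.name} charge={ion.total_charge}"]
    for a in ion.atoms:
        x, y, z = a.position
        out.append(
            f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f} {a.partial_charge:12.6f}"
        )
    path.write_text("\n".join(out) + "\n")


def write_mobcal_input(ion: MolecularIon, path: str | Path) -> None:
    """Emit a MOBCAL-style coordinate record for cross-checking legacy tools.

    Layout: atom count and charge scale header, then per-atom x y z q m rows.
    """
    path = Path(path)
    out = [
        f"{ion.name}",
        f"{len(ion)} 1",
        "ang",
        "calc",
        "1.0000",
    ]
    for a in ion.atoms:
        x, y, z = a.position
        out.append(
            f"{x:12.6f} {y:12.6f} {z:12.6f} {a.partial_charge:12.6f} {a.mass:10.4f}"
        )
    path.write_text("\n".join(out) + "\n")


# -- rigid motion ------------------------------------------------------------


def rigid_transform(
    ion: MolecularIon,
    rotation: np.ndarray,
    translation: Iterable[float] = (0.0, 0.0, 0.0),
) -> MolecularIon:
    """Apply ``x -> R x + t`` to every atom; charges and masses unchanged.

    ``rotation`` must be orthonormal to 1e-10 (``||R^T R - I||`` max norm).
    """
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.max(np.abs(rot.T @ rot - np.eye(3))) > 1e-10:
        raise ValueError("rotation matrix is not orthonormal")
    t = np.asarray(tuple(translation), dtype=float)
    atoms = tuple(
        replace(a, position=rot @ a.position + t) for a in ion.atoms
    )
    return replace(ion, atoms=atoms)
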