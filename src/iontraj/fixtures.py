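"""Template geometries for the benchmark ion families.

These builders stand in for quantum-chemically optimized structures: they use
textbook bond lengths and angles (C-C 1.54 A aliphatic / 1.39 A aromatic,
C-H 1.09 A, O-H 0.96-0.98 A, tetrahedral angles) and fixed per-atom
partial-charge templates that sum to the +1 e total charge of each ion.
They are idealized approximations, adequate for studying the method itself
(trends, invariances, error statistics), not for reproducing any particular
optimized structure.

Families covered:

* ``build_water_cluster(n)`` -- the protonated water clusters
  (H3O+)(H2O)n, n = 0..5, that form the reactant-ion peak in positive-mode
  IMS at atmospheric pressure.
* ``build_benzene`` / ``build_toluene`` -- small aromatics ionized by
  electron abstraction, bare or clustered with one water.
* ``build_alkane(n_carbons)`` -- n-alkanes C6..C10 (also electron
  abstraction), optionally with one water attached at the chain midpoint.
"""

from __future__ import annotations

import numpy as np

from .structures import MolecularIon, _make_ion

__all__ = [
    "build_water_cluster",
    "build_benzene",
    "build_toluene",
    "build_alkane",
]

# bond lengths, Angstrom
_OH_HYDRONIUM = 0.98
_OH_WATER = 0.96
_CC_AROMATIC = 1.39
_CC_ALIPHATIC = 1.54
_CH = 1.09
_CC_METHYL = 1.51
_OO_HBOND = 2.70  # hydrogen-bond O-O separation in the clusters
_HOH_WATER = np.deg2rad(104.5)
_TETRA = np.arccos(-1.0 / 3.0)  # 109.471 deg

# partial-charge templates, e
_Q_HYDRONIUM_O = -0.40
_Q_HYDRONIUM_H = (1.0 - _Q_HYDRONIUM_O) / 3.0
_Q_WATER_O = -0.66
_Q_WATER_H = 0.33
_Q_AROMATIC_H = 0.20
_Q_ALKANE_H = 0.06


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vector along *axis* plus two perpendicular unit vectors."""
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return w, u, v


def _water_atoms(
    o_pos: np.ndarray, axis: np.ndarray, roll: float = 0.0
) -> tuple[list[str], list[np.ndarray]]:
    """A water molecule with O at *o_pos* and both H on the *axis* side.

    *axis* is the direction the C2 symmetry axis points (away from whatever
    the water is attached to); *roll* rotates the H-H plane about it.
    """
    w, u, v = _orthonormal_frame(axis)
    p = np.cos(roll) * u + np.sin(roll) * v
    half = _HOH_WATER / 2.0
    d1 = np.cos(half) * w + np.sin(half) * p
    d2 = np.cos(half) * w - np.sin(half) * p
    return ["O", "H", "H"], [o_pos, o_pos + _OH_WATER * d1, o_pos + _OH_WATER * d2]


def _append_water(
    elements: list[str],
    positions: list[np.ndarray],
    charges: list[float],
    o_pos: np.ndarray,
    axis: np.ndarray,
    roll: float = 0.0,
) -> None:
    els, pos = _water_atoms(np.asarray(o_pos, float), np.asarray(axis, float), roll)
    elements.extend(els)
    positions.extend(pos)
    charges.extend([_Q_WATER_O, _Q_WATER_H, _Q_WATER_H])


def build_water_cluster(n: int) -> MolecularIon:
    """The protonated water cluster (H3O+)(H2O)n, total charge +1 e.

    The hydronium core is pyramidal (O-H 0.98 A, H-O-H 111.7 deg); up to
    three waters hydrogen-bond to the hydronium hydrogens at O-O 2.70 A,
    further waters attach to first-shell water hydrogens (second solvation
    shell).  Nominal mass is 19 + 18 n Da.
    """
    if n < 0:
        raise ValueError("cluster size n must be >= 0")
    if n > 5:
        raise ValueError("cluster size n must be <= 5 (typical IMS range)")

    # hydronium: umbrella geometry, lone pair along -z
    hoh = np.deg2rad(111.7)
    cos_beta = np.sqrt((2.0 * np.cos(hoh) + 1.0) / 3.0)
    beta = np.arccos(cos_beta)
    elements: list[str] = ["O"]
    positions: list[np.ndarray] = [np.zeros(3)]
    charges: list[float] = [_Q_HYDRONIUM_O]
    oh_dirs = []
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        d = np.array(
            [np.sin(beta) * np.cos(phi), np.sin(beta) * np.sin(phi), np.cos(beta)]
        )
        oh_dirs.append(d)
        elements.append("H")
        positions.append(_OH_HYDRONIUM * d)
        charges.append(_Q_HYDRONIUM_H)

    first_shell_o: list[tuple[np.ndarray, np.ndarray]] = []  # (O pos, axis)
    for k in range(min(n, 3)):
        o_pos = _OO_HBOND * oh_dirs[k]
        _append_water(elements, positions, charges, o_pos, oh_dirs[k], roll=0.3)
        first_shell_o.append((o_pos, oh_dirs[k]))
    for k in range(max(0, n - 3)):
        # attach to one hydrogen of first-shell water k, slightly longer O-O
        o_parent, axis = first_shell_o[k]
        _, pos = _water_atoms(o_parent, axis, roll=0.3)
        h_dir = (pos[1] - o_parent) / np.linalg.norm(pos[1] - o_parent)
        o_pos = o_parent + 2.85 * h_dir
        _append_water(elements, positions, charges, o_pos, h_dir, roll=1.1)

    name = "H3O+" if n == 0 else f"(H3O+)(H2O){n}"
    return _make_ion(name, elements, np.array(positions), charges, total_charge=1)


def _ring(
    n_ring_h: int = 6, substituted: tuple[int, ...] = ()
) -> tuple[list[str], list[np.ndarray]]:
    """Planar C6 ring in the xy-plane with H on unsubstituted positions."""
    elements: list[str] = []
    positions: list[np.ndarray] = []
    for k in range(6):
        phi = 2.0 * np.pi * k / 6.0
        d = np.array([np.cos(phi), np.sin(phi), 0.0])
        elements.append("C")
        positions.append(_CC_AROMATIC * d)
        if k not in substituted:
            elements.append("H")
            positions.append((_CC_AROMATIC + _CH) * d)
    return elements, positions


def _assign_uniform(elements: list[str], q_h: float, total: float) -> list[float]:
    """Charges: every H gets *q_h*; carbons share the remainder of *total*."""
    n_h = sum(1 for e in elements if e == "H")
    n_c = sum(1 for e in elements if e == "C")
    q_c = (total - q_h * n_h) / n_c
    return [q_h if e == "H" else q_c for e in elements]


def build_benzene(with_water: bool = False) -> MolecularIon:
    """Benzene radical cation C6H6+ (electron abstraction), optionally with
    one water on the ring axis ~3 A above the centroid."""
    elements, positions = _ring()
    charges = _assign_uniform(elements, _Q_AROMATIC_H, 1.0)
    if with_water:
        _append_water(
            elements, positions, charges, np.array([0.0, 0.0, 3.0]), [0.0, 0.0, 1.0]
        )
    name = "benzene+H2O" if with_water else "benzene"
    return _make_ion(name, elements, np.array(positions), charges, total_charge=1)


def build_toluene(with_water: bool = False) -> MolecularIon:
    """Toluene radical cation C7H8+, optionally with one axial water."""
    elements, positions = _ring(substituted=(0,))
    cme = np.array([_CC_AROMATIC + _CC_METHYL, 0.0, 0.0])
    elements.append("C")
    positions.append(cme)
    # methyl hydrogens: tetrahedral about the ring C-C bond (+x)
    for phi in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
        d = np.array(
            [
                -np.cos(_TETRA),
                np.sin(_TETRA) * np.cos(phi),
                np.sin(_TETRA) * np.sin(phi),
            ]
        )
        d = np.array([abs(d[0]), d[1], d[2]])  # point away from the ring
        elements.append("H")
        positions.append(cme + _CH * d)
    charges = _assign_uniform(elements, _Q_AROMATIC_H, 1.0)
    if with_water:
        _append_water(
            elements, positions, charges, np.array([0.0, 0.0, 3.0]), [0.0, 0.0, 1.0]
        )
    name = "toluene+H2O" if with_water else "toluene"
    return _make_ion(name, elements, np.array(positions), charges, total_charge=1)


_ALKANE_NAMES = {6: "hexane", 7: "heptane", 8: "octane", 9: "nonane", 10: "decane"}


def build_alkane(n_carbons: int, with_water: bool = False) -> MolecularIon:
    """All-anti n-alkane CnH2n+2 radical cation, C6..C10.

    With ``with_water`` a single water molecule sits ~3 A above the midpoint
    carbon, its hydrogens pointing away from the chain.
    """
    if not 6 <= n_carbons <= 10:
        raise ValueError("n_carbons must be between 6 and 10")

    half = _TETRA / 2.0
    dx = _CC_ALIPHATIC * np.sin(half)
    dy = _CC_ALIPHATIC * np.cos(half)
    backbone = [
        np.array([i * dx, (dy / 2.0) * (-1.0) ** i, 0.0]) for i in range(n_carbons)
    ]

    elements: list[str] = []
    positions: list[np.ndarray] = []
    sin_a, cos_a = np.sin(half), np.cos(half)
    for i, c in enumerate(backbone):
        elements.append("C")
        positions.append(c)
        neighbors = [backbone[j] for j in (i - 1, i + 1) if 0 <= j < n_carbons]
        if len(neighbors) == 2:
            e1 = (neighbors[0] - c) / _CC_ALIPHATIC
            e2 = (neighbors[1] - c) / _CC_ALIPHATIC
            bis = e1 + e2
            bis /= np.linalg.norm(bis)
            for sz in (+1.0, -1.0):
                d = -cos_a * bis + sz * sin_a * np.array([0.0, 0.0, 1.0])
                elements.append("H")
                positions.append(c + _CH * d)
        else:  # terminal CH3
            e = (neighbors[0] - c) / _CC_ALIPHATIC
            _, u, v = _orthonormal_frame(e)
            for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
                # H-C-C angle tetrahedral: component -1/3 along the C-C bond
                d = (-1.0 / 3.0) * e + (np.sqrt(8.0) / 3.0) * (
                    np.cos(phi) * u + np.sin(phi) * v
                )
                elements.append("H")
                positions.append(c + _CH * d)

    charges = _assign_uniform(elements, _Q_ALKANE_H, 1.0)

    if with_water:
        mid = backbone[(n_carbons - 1) // 2]
        o_pos = mid + np.array([dx / 2.0, 0.0, 3.0])
        _append_water(elements, positions, charges, o_pos, [0.0, 0.0, 1.0])

    base = _ALKANE_NAMES[n_carbons]
    name = f"{base}+H2O" if with_water else base
    return _make_ion(name, elements, np.array(positions), charges, total_charge=1)
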