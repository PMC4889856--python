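"""Geometry domain types, xyzq file round-trips and the fixture builders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from iontraj.structures import (
    Atom,
    ChargeSumError,
    MolecularIon,
    XYZQParseError,
    atomic_mass,
    read_xyzq,
    rigid_transform,
    write_xyzq,
)
from iontraj.fixtures import (
    build_alkane,
    build_benzene,
    build_toluene,
    build_water_cluster,
)

ALL_BUILDERS = (
    [lambda n=n: build_water_cluster(n) for n in range(6)]
    + [build_benzene, lambda: build_benzene(True)]
    + [build_toluene, lambda: build_toluene(True)]
    + [lambda n=n: build_alkane(n) for n in (6, 8, 10)]
    + [lambda n=n: build_alkane(n, with_water=True) for n in (6, 8, 10)]
)


class TestDomainTypes:
    def test_single_nitrogen_atom_ion(self, tmp_path):
        p = tmp_path / "n.xyzq"
        p.write_text("1\nbare nitrogen charge=1\nN 0.0 0.0 0.0 1.0\n")
        ion = read_xyzq(p)
        assert len(ion) == 1
        assert ion.mass == pytest.approx(14.007, abs=1e-3)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            atomic_mass("Xx")

    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            Atom("H", np.array([0.0, np.nan, 0.0]))

    def test_empty_ion_rejected(self):
        with pytest.raises(ValueError, match="at least one atom"):
            MolecularIon("empty", ())

    def test_charge_sum_invariant(self):
        atoms = (
            Atom("O", np.zeros(3), -0.5),
            Atom("H", np.array([1.0, 0.0, 0.0]), 0.45),
        )
        with pytest.raises(ChargeSumError, match=r"-0\.05"):
            MolecularIon("bad", atoms, total_charge=0)

    def test_mass_is_sum_of_atomic_masses(self):
        ion = build_benzene()
        assert ion.mass == pytest.approx(6 * atomic_mass("C") + 6 * atomic_mass("H"),
                                         abs=1e-6)


class TestFileIO:
    def test_round_trip_preserves_numbers(self, tmp_path):
        ion = build_water_cluster(2)
        p = tmp_path / "w2.xyzq"
        write_xyzq(ion, p)
        back = read_xyzq(p)
        assert back.name == ion.name
        assert back.total_charge == ion.total_charge
        assert np.allclose(back.positions, ion.positions, atol=1e-6)
        assert np.allclose(back.partial_charges, ion.partial_charges, atol=1e-6)
        # second pass is byte-identical (fixed-width formatting)
        p2 = tmp_path / "w2b.xyzq"
        write_xyzq(back, p2)
        assert p.read_text() == p2.read_text()

    def test_charge_sum_violation_reported(self, tmp_path):
        p = tmp_path / "bad.xyzq"
        p.write_text("1\nion charge=1\nN 0 0 0 0.95\n")
        with pytest.raises(ChargeSumError, match=r"0\.95"):
            read_xyzq(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.xyzq"
        p.write_text("2\nion charge=0\nN 0 0 0 0.0\nO 1 zz 0 0.0\n")
        with pytest.raises(XYZQParseError, match="line 4"):
            read_xyzq(p)

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "short.xyzq"
        p.write_text("3\nion charge=0\nN 0 0 0 0.0\n")
        with pytest.raises(XYZQParseError, match="3 atoms"):
            read_xyzq(p)


class TestFixtureBuilders:
    @pytest.mark.parametrize("builder", ALL_BUILDERS)
    def test_invariants_hold(self, builder):
        ion = builder()
        assert abs(ion.partial_charges.sum() - ion.total_charge) <= 0.01
        assert np.all(ion.masses > 0)
        assert pdist(ion.positions).min() >= 0.9

    @pytest.mark.parametrize("n", range(6))
    def test_water_cluster_nominal_mass(self, n):
        ion = build_water_cluster(n)
        assert len(ion) == 4 + 3 * n
        assert ion.nominal_mass == 19 + 18 * n

    def test_largest_rip_cluster_is_91_da(self):
        assert build_water_cluster(4).nominal_mass == 91

    def test_cluster_hydrogen_bond_distances(self):
        ion = build_water_cluster(3)
        o_positions = ion.positions[[a == "O" for a in ion.elements]]
        hydronium_o = o_positions[0]
        shell = np.linalg.norm(o_positions[1:] - hydronium_o, axis=1)
        assert np.all((shell >= 2.6) & (shell <= 2.9))

    def test_water_cluster_domain(self):
        with pytest.raises(ValueError):
            build_water_cluster(-1)
        with pytest.raises(ValueError):
            build_water_cluster(6)

    def test_benzene_formula(self):
        ion = build_benzene()
        assert len(ion) == 12
        assert ion.mass == pytest.approx(78.11, abs=0.01)
        assert build_benzene(True).partial_charges.sum() == pytest.approx(1.0)
        assert len(build_benzene(True)) == 15

    def test_toluene_atom_counts(self):
        assert len(build_toluene()) == 15
        assert len(build_toluene(True)) == 18

    @pytest.mark.parametrize("n,n_atoms,mass", [(6, 20, 86.18), (10, 32, 142.28)])
    def test_alkane_formula(self, n, n_atoms, mass):
        ion = build_alkane(n)
        assert len(ion) == n_atoms
        assert ion.mass == pytest.approx(mass, abs=0.01)

    def test_decane_with_water_atom_count(self):
        assert len(build_alkane(10, with_water=True)) == 35

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_water_clears_the_alkane(self, n):
        ion = build_alkane(n, with_water=True)
        assert cdist(ion.positions[:-3], ion.positions[-3:]).min() >= 2.0

    def test_alkane_domain(self):
        for n in (5, 11):
            with pytest.raises(ValueError):
                build_alkane(n)


class TestRigidTransform:
    def test_identity(self):
        ion = build_water_cluster(1)
        moved = rigid_transform(ion, np.eye(3))
        assert np.allclose(moved.positions, ion.positions)

    def test_axis_mapping_quarter_turn(self):
        ion = MolecularIon(
            "pair",
            (Atom("N", np.zeros(3), 0.0), Atom("N", np.array([2.0, 0.0, 0.0]), 0.0)),
            total_charge=0,
        )
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = rigid_transform(ion, rot)
        assert np.allclose(moved.positions[1], [0.0, 2.0, 0.0], atol=1e-12)

    def test_non_orthonormal_rejected(self):
        ion = build_benzene()
        with pytest.raises(ValueError, match="orthonormal"):
            rigid_transform(ion, np.eye(3) * 1.001)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_distances_charges_preserved(self, seed):
        ion = build_water_cluster(2)
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=5.0, size=3)
        moved = rigid_transform(ion, rot, t)
        assert np.allclose(pdist(moved.positions), pdist(ion.positions), atol=1e-9)
        assert np.array_equal(moved.partial_charges, ion.partial_charges)
        assert np.array_equal(moved.masses, ion.masses)
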