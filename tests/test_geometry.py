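"""Geometry descriptors and the exact Coulomb repulsion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coulombfit.constants import HARTREE_TO_INVCM
from coulombfit.geometry import (AtomSpec, CoordinateSpec,
                                 DegenerateGeometryError, MolecularFrame,
                                 bond_triple_to_angle,
                                 bond_triple_to_distances, jacobi_frame,
                                 jacobi_to_distances, nuclear_repulsion,
                                 pairwise_distances, read_xyz, torsion_frame,
                                 write_xyz)

H = AtomSpec.from_symbol("H")
HE = AtomSpec.from_symbol("He")


class TestPairwiseDistances:
    def test_unit_displacement(self):
        f = MolecularFrame((H, H), [[0, 0, 0], [0, 0, 1.0]])
        assert pairwise_distances(f) == [(0, 1, 1.0)]

    def test_collinear_triple(self):
        f = MolecularFrame((H, H, H), [[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        assert [d for *_ij, d in pairwise_distances(f)] == [1.0, 2.0, 1.0]

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(-3, 3, size=(5, 3))
        f = MolecularFrame((H,) * 5, pos)
        for i, j, d in pairwise_distances(f):
            ref = math.sqrt(sum((pos[i, k] - pos[j, k]) ** 2 for k in range(3)))
            assert abs(d - ref) < 1e-12

    def test_coincident_atoms_rejected(self):
        f = MolecularFrame((H, H), [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            pairwise_distances(f)


class TestNuclearRepulsion:
    def test_h2plus_at_one_bohr(self):
        f = MolecularFrame((H, H), [[0, 0, 0], [0, 0, 1.0]])
        assert nuclear_repulsion(f) == pytest.approx(1.0, abs=1e-15)

    def test_three_pair_hand_sum(self):
        # collinear He-H-He, both He-H = 1 bohr: 2*(2/1) + 4/2 = 6 Eh
        f = MolecularFrame((HE, H, HE), [[0, 0, -1.0], [0, 0, 0], [0, 0, 1.0]])
        assert nuclear_repulsion(f) == pytest.approx(6.0, abs=1e-14)

    def test_h2_at_equilibrium_in_wavenumbers(self):
        f = MolecularFrame((H, H), [[0, 0, 0], [0, 0, 1.40]])
        v = nuclear_repulsion(f)
        assert v == pytest.approx(1.0 / 1.40, rel=1e-12)
        assert v * HARTREE_TO_INVCM == pytest.approx(156767.6, abs=0.1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-2, 2, size=(4, 3))
        f = MolecularFrame((H, HE, H, HE), pos)
        v0 = nuclear_repulsion(f)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = f.rotated(Q).translated(rng.uniform(-5, 5, 3))
        assert nuclear_repulsion(moved) == pytest.approx(v0, abs=1e-10)

    def test_decreasing_in_each_distance(self):
        for d in (0.5, 1.0, 2.0, 4.0):
            f1 = MolecularFrame((H, H), [[0, 0, 0], [0, 0, d]])
            f2 = MolecularFrame((H, H), [[0, 0, 0], [0, 0, d + 0.1]])
            assert nuclear_repulsion(f2) < nuclear_repulsion(f1)


class TestJacobi:
    def test_perpendicular_equal_masses(self):
        d_ab, d_ca, d_cb = jacobi_to_distances(2.0, 1.0, 90.0, (1.0, 1.0))
        assert d_ab == 1.0
        assert d_ca == pytest.approx(math.sqrt(4.25), abs=1e-7)
        assert d_cb == pytest.approx(math.sqrt(4.25), abs=1e-7)

    def test_collinear_equal_masses(self):
        _, d_ca, d_cb = jacobi_to_distances(2.0, 1.0, 180.0, (1.0, 1.0))
        assert d_ca == pytest.approx(2.5, abs=1e-12)
        assert d_cb == pytest.approx(1.5, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 180.0])
    @pytest.mark.parametrize("masses", [(1.0, 1.0), (4.0, 1.0)])
    def test_collinear_distance_additivity(self, theta, masses):
        d = sorted(jacobi_to_distances(2.5, 1.2, theta, masses))
        assert d[2] == pytest.approx(d[0] + d[1], abs=1e-10)

    def test_mirror_symmetry_for_equal_masses(self):
        _, ca1, cb1 = jacobi_to_distances(3.0, 1.1, 40.0, (1.0, 1.0))
        _, ca2, cb2 = jacobi_to_distances(3.0, 1.1, 140.0, (1.0, 1.0))
        assert ca1 == pytest.approx(cb2, abs=1e-12)
        assert cb1 == pytest.approx(ca2, abs=1e-12)

    def test_frame_path_equivalence(self):
        """Jacobi distances + pair sum == explicit Cartesian frame V_nu."""
        atoms = (HE, H, HE)
        spec = CoordinateSpec("jacobi_3d", atoms)
        rng = np.random.default_rng(7)
        for _ in range(20):
            R, r = rng.uniform(0.5, 6.0, 2)
            th = rng.uniform(0.0, 180.0)
            v1 = spec.vnu([[R, r, th]])[0]
            v2 = nuclear_repulsion(jacobi_frame(R, r, th, atoms))
            assert v1 == pytest.approx(v2, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jacobi_to_distances(-1.0, 1.0, 90.0, (1.0, 1.0))
        with pytest.raises(ValueError):
            jacobi_to_distances(1.0, 1.0, 200.0, (1.0, 1.0))


class TestBondTriple:
    def test_collinear_accepted(self):
        assert bond_triple_to_distances(1.0, 1.0, 2.0) == (1.0, 1.0, 2.0)

    def test_equilateral_angle(self):
        assert bond_triple_to_angle(1.0, 1.0, 1.0) == pytest.approx(60.0)

    def test_right_triangle(self):
        assert bond_triple_to_angle(3.0, 4.0, 5.0) == pytest.approx(90.0)

    def test_violation_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            bond_triple_to_distances(1.0, 1.0, 2.1)


class TestTorsion:
    @pytest.fixture()
    def ethane(self):
        from coulombfit.synthetic import ethane_frame
        return ethane_frame()

    @pytest.mark.parametrize("phi", [0.0, 360.0])
    def test_identity_and_periodicity(self, ethane, phi):
        frame, dih, rot = ethane
        out = torsion_frame(frame, dih, phi, rot)
        assert np.allclose(out.positions, frame.positions, atol=1e-10)

    def test_rigid_rotation_preserves_bonds(self, ethane):
        frame, dih, rot = ethane
        out = torsion_frame(frame, dih, 47.3, rot)
        for i, j, d in pairwise_distances(frame):
            if i in rot and j in rot:
                d2 = np.linalg.norm(out.positions[j] - out.positions[i])
                assert d2 == pytest.approx(d, abs=1e-10)

    def test_vnu_period_120_for_symmetric_methyls(self, ethane):
        frame, dih, rot = ethane
        spec = CoordinateSpec("torsion", frame.atoms,
                              {"template": frame, "dihedral_atoms": dih,
                               "rotate_atoms": rot})
        phi = np.linspace(-180.0, 180.0, 25).reshape(-1, 1)
        v = spec.vnu(phi)
        v_shift = spec.vnu(phi + 120.0)
        assert np.allclose(v, v_shift, atol=1e-10)


class TestXYZ:
    def test_round_trip(self, tmp_path):
        f = MolecularFrame((H, HE), [[0, 0, 0], [0.1, -0.2, 1.9]])
        p = tmp_path / "frame.xyz"
        write_xyz(f, p, comment="test frame")
        g = read_xyz(p)
        assert [a.symbol for a in g.atoms] == ["H", "He"]
        assert np.allclose(g.positions, f.positions, atol=1e-10)

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("not-a-count\ncomment\n")
        with pytest.raises(ValueError):
            read_xyz(p)


class TestAtomSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            AtomSpec("X", Z=-1.0, mass=1.0)
        with pytest.raises(ValueError):
            AtomSpec("X", Z=1.0, mass=0.0)

    def test_element_lookup(self):
        assert HE.Z == 2
        assert HE.mass == pytest.approx(4.002602)
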