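"""Energy tables, Coulomb subtraction/addition and train/test splitting."""

import numpy as np
import pytest

from coulombfit.constants import HARTREE_TO_INVCM, cm_to_hartree
from coulombfit.dataset import (EnergyTable, SplitSpec, add_nuclear,
                                add_united_atom, read_table, split_train_test,
                                subtract_nuclear, write_table)
from coulombfit.geometry import AtomSpec, CoordinateSpec
from coulombfit.synthetic import generate_diatomic_table, h2plus_like

H2 = CoordinateSpec("diatomic_R", (AtomSpec.from_symbol("H"),
                                   AtomSpec.from_symbol("H")))


def diatomic_table(R_bohr, V=None, Eel=None, **kw):
    return EnergyTable(H2, np.asarray(R_bohr, float).reshape(-1, 1),
                       V=V, Eel=Eel, **kw)


class TestCoulombSubtraction:
    def test_explicit_arithmetic(self):
        # V = 100000 cm^-1 at the distance where V_nu = 1 Eh = 219474.63 cm^-1
        t = diatomic_table([1.0], V=[cm_to_hartree(100000.0)])
        out = subtract_nuclear(t)
        assert out.Eel_cm()[0] == pytest.approx(100000.0 - 219474.6313632,
                                                abs=1e-6)

    def test_round_trip_identity(self, h2plus_table):
        t = h2plus_table.copy_with(Eel=None)
        back = add_nuclear(subtract_nuclear(t))
        assert np.nanmax(np.abs(back.V - h2plus_table.V)) * HARTREE_TO_INVCM < 1e-9

    def test_geometry_oracle(self):
        # V = -0.1 Eh at R = 1 bohr (V_nu = 1 Eh) -> E_el = -1.1 Eh
        t = diatomic_table([1.0], V=[-0.1])
        assert subtract_nuclear(t).Eel[0] == pytest.approx(-1.1, abs=1e-12)

    def test_add_requires_eel(self):
        t = diatomic_table([1.0, 2.0], V=[-0.1, -0.2])
        with pytest.raises(ValueError):
            add_nuclear(t)

    def test_consistency_enforced(self):
        with pytest.raises(ValueError, match="V != E_el"):
            diatomic_table([1.0], V=[-0.1], Eel=[-0.5])


class TestUnitedAtom:
    def test_hydrogenic_value(self, h2plus_table):
        t = add_united_atom(h2plus_table, "hydrogenic", n_electrons=1)
        assert t.Eel[0] == pytest.approx(-2.0, abs=1e-14)
        assert t.Eel_cm()[0] == pytest.approx(-438949.262726, abs=1e-4)
        assert t.is_united_atom[0]
        assert len(t) == len(h2plus_table) + 1

    def test_explicit_value(self, h2plus_table):
        t = add_united_atom(h2plus_table, -1.75)
        assert t.Eel[0] == -1.75

    def test_hydrogenic_guard(self, h2plus_table):
        with pytest.raises(ValueError, match="one-electron"):
            add_united_atom(h2plus_table, "hydrogenic", n_electrons=2)

    def test_forced_into_training(self, h2plus_table_ua):
        train, test = split_train_test(h2plus_table_ua,
                                       SplitSpec(0.8, "random", seed=5))
        assert 0 in train and 0 not in test


class TestSplit:
    @pytest.mark.parametrize("n,frac,n_train,n_test", [
        (81, 0.9, 72, 9),      # the conventional 9:1 split of an 81-point set
        (10, 0.8, 8, 2),
        (401, 0.8, 320, 81),
    ])
    def test_counts(self, n, frac, n_train, n_test):
        t = diatomic_table(np.linspace(0.5, 10, n), Eel=np.linspace(-2, -0.5, n))
        train, test = split_train_test(t, SplitSpec(frac, "random", seed=1))
        assert (len(train), len(test)) == (n_train, n_test)
        merged = np.sort(np.concatenate([train, test]))
        assert np.array_equal(merged, np.arange(n))

    def test_deterministic_and_seed_sensitive(self, h2plus_table):
        s = SplitSpec(0.8, "random", seed=42)
        a1 = split_train_test(h2plus_table, s)
        a2 = split_train_test(h2plus_table, s)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])
        b = split_train_test(h2plus_table, SplitSpec(0.8, "random", seed=43))
        assert not np.array_equal(a1[0], b[0])

    def test_manual(self):
        t = diatomic_table(np.linspace(1, 5, 10), Eel=np.linspace(-2, -1, 10))
        train, test = split_train_test(
            t, SplitSpec(0.5, "manual", manual_indices=(0, 2, 4, 6)))
        assert np.array_equal(train, [0, 2, 4, 6])
        assert np.array_equal(test, [1, 3, 5, 7, 8, 9])
        with pytest.raises(IndexError):
            split_train_test(t, SplitSpec(0.5, "manual", manual_indices=(99,)))

    def test_stratified_covers_steep_decile(self, h2plus_table):
        """The stratified strategy puts the steep repulsive records in training."""
        spec = SplitSpec(0.8, "stratified_energy", seed=3, density_boost=8)
        train, _ = split_train_test(h2plus_table, spec)
        # top-slope decile of the monotone-wall curve is at smallest R
        slopes = np.abs(np.gradient(h2plus_table.V, h2plus_table.coords[:, 0]))
        decile = np.argsort(slopes)[::-1][:int(np.ceil(0.1 * len(h2plus_table)))]
        assert len(np.intersect1d(train, decile)) >= 8

    def test_degenerate_rejected(self):
        t = diatomic_table([1.0, 2.0], Eel=[-2.0, -1.0])
        with pytest.raises(ValueError):
            split_train_test(t, SplitSpec(0.05, "random", seed=1))


class TestTableValidation:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            diatomic_table([1.0, 1.0], Eel=[-2.0, -2.0])

    def test_needs_some_energy(self):
        with pytest.raises(ValueError, match="at least one"):
            diatomic_table([1.0])


class TestCSV:
    def test_round_trip(self, tmp_path):
        t = diatomic_table([1.0, 2.0, 3.0], V=[-0.1, -0.4, -0.45])
        p = tmp_path / "t.csv"
        write_table(t, p)
        back = read_table(p)
        assert np.allclose(back.coords, t.coords, atol=1e-12)
        assert np.allclose(back.V, t.V, atol=1e-12)

    def test_unit_equivalence(self, tmp_path, h2plus_table):
        """angstrom/cm-1 and bohr/hartree files load to identical tables."""
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_table(h2plus_table, p1, "angstrom", "cm-1")
        write_table(h2plus_table, p2, "bohr", "hartree")
        t1, t2 = read_table(p1), read_table(p2)
        assert np.allclose(t1.coords, t2.coords, rtol=1e-12, atol=0)
        assert np.allclose(t1.V, t2.V, rtol=1e-12, atol=1e-15)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# kind=diatomic_R\n# atoms=H,H\nR,V\n1.0,-0.1\n2.0,oops\n")
        with pytest.raises(ValueError, match="line 5"):
            read_table(p)

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# kind=diatomic_R\n# atoms=H,H\nR\n1.0\n")
        with pytest.raises(ValueError, match="V.*Eel|Eel.*V"):
            read_table(p)

    def test_united_atom_round_trip(self, tmp_path, h2plus_table_ua):
        p = tmp_path / "ua.csv"
        write_table(h2plus_table_ua, p)
        back = read_table(p)
        assert back.is_united_atom[0]
        assert np.isnan(back.V[0])
        assert back.Eel[0] == pytest.approx(-2.0, abs=1e-12)
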