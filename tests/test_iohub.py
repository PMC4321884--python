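"""I/O round trips, reflection reduction and symmetry bookkeeping."""

import numpy as np
import pytest

import gemmi

from mrllg import iohub
from mrllg.iohub import (AtomicModel, FormatError, ValidationError,
                         build_reflection_set, get_space_group, read_model,
                         read_reflections, write_model)

PDB_3ATOMS = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 15.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00 20.00           C
ATOM      3  O   ALA A   1       3.500   3.000   3.000  1.00 26.32           O
END
"""

PDB_ALTLOC = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 15.00           N
ATOM      2  CA AALA A   1       2.500   2.000   3.000  0.60 20.00           C
ATOM      3  CA BALA A   1       2.600   2.100   3.000  0.40 20.00           C
ATOM      4  C   ALA A   1       3.500   3.000   3.000  1.00 18.00           C
END
"""


def _simple_model(n=3):
    return AtomicModel(
        element=["C"] * n, xyz=np.arange(3 * n).reshape(n, 3) * 1.0,
        b=np.full(n, 20.0), occ=np.ones(n), chain=["A"] * n,
        resnum=np.arange(1, n + 1), resname=["ALA"] * n,
        atomname=["CA"] * n, cell=(20, 20, 20, 90, 90, 90), space_group="P1")


class TestReadModel:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(PDB_3ATOMS)
        m = read_model(p)
        assert m.n_atoms == 3
        assert sorted(m.element.tolist()) == ["C", "N", "O"]
        assert m.b_column_meaning == "unknown"

    def test_error_estimate_flag_preserves_values(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(PDB_3ATOMS)
        m = read_model(p, b_column_meaning="error_estimate")
        # the numbers are exposed as |dr| in A, not reinterpreted
        assert m.b_column_meaning == "error_estimate"
        assert m.b == pytest.approx([15.0, 20.0, 26.32])

    def test_altloc_keeps_first_only(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(PDB_ALTLOC)
        m = read_model(p)
        assert m.n_atoms == 3
        assert (m.atomname == "CA").sum() == 1
        ca = m.xyz[m.atomname == "CA"][0]
        assert ca == pytest.approx([2.5, 2.0, 3.0])

    def test_unparseable_file(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM garbage\n")
        with pytest.raises((FormatError, ValidationError)):
            read_model(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_model(tmp_path / "nope.pdb")


class TestWriteModel:
    def test_round_trip_precision(self, tmp_path, chain60):
        p = tmp_path / "out.pdb"
        write_model(chain60, p)
        back = read_model(p, b_column_meaning="b_factor")
        assert back.n_atoms == chain60.n_atoms
        assert np.max(np.abs(back.xyz - chain60.xyz)) <= 5e-4
        assert np.max(np.abs(back.b - chain60.b)) <= 5e-3

    def test_fixed_columns(self, tmp_path):
        m = _simple_model(1)
        m.b = np.array([26.32])
        p = tmp_path / "m.pdb"
        write_model(m, p)
        atom_line = [l for l in p.read_text().splitlines()
                     if l.startswith(("ATOM", "HETATM"))][0]
        assert atom_line[60:66] == " 26.32"

    def test_empty_model_rejected(self, tmp_path):
        from mrllg.prep import empty_model
        with pytest.raises(ValidationError):
            write_model(empty_model((20, 20, 20, 90, 90, 90), "P1"),
                        tmp_path / "e.pdb")


class TestModelInvariants:
    def test_negative_b_rejected(self):
        with pytest.raises(ValidationError):
            m = _simple_model()
            m.b = np.array([1.0, -2.0, 3.0])
            m.validate()

    def test_occupancy_range(self):
        with pytest.raises(ValidationError):
            AtomicModel(element=["C"], xyz=[[0, 0, 0]], b=[10], occ=[1.5],
                        chain=["A"], resnum=[1], resname=["ALA"],
                        atomname=["CA"], cell=(10, 10, 10, 90, 90, 90),
                        space_group="P1")

    def test_bad_cell(self):
        with pytest.raises(ValidationError):
            AtomicModel(element=["C"], xyz=[[0, 0, 0]], b=[10], occ=[1],
                        chain=["A"], resnum=[1], resname=["ALA"],
                        atomname=["CA"], cell=(10, -1, 10, 90, 90, 90),
                        space_group="P1")

    def test_unsupported_space_group(self):
        with pytest.raises(ValidationError):
            get_space_group("I 41 3 2")


class TestReflections:
    def test_friedel_merge_p1(self, tmp_path):
        p = tmp_path / "r.hkl"
        p.write_text("1 0 0 5.0\n-1 0 0 7.0\n")
        rs = read_reflections(p, (10, 10, 10, 90, 90, 90), "P1")
        assert rs.n_reflections == 1
        assert rs.f[0] == pytest.approx(6.0)  # merged by averaging

    def test_centric_h00_in_p212121(self):
        # (4,0,0) survives the screw-axis absence rule (even h) and is
        # fixed up to Friedel by a reciprocal-space twofold -> centric
        rs = build_reflection_set([[4, 0, 0], [1, 2, 3]], [1.0, 1.0], None,
                                  (20, 25, 30, 90, 90, 90), "P212121")
        lookup = {tuple(h): bool(c) for h, c in zip(rs.hkl.tolist(), rs.centric)}
        assert lookup[(4, 0, 0)] is True
        assert lookup[(1, 2, 3)] is False

    def test_systematic_absences_dropped(self):
        # odd (h,0,0) is extinguished by the 2_1 screw along a
        from mrllg.iohub import ValidationError
        with pytest.raises(ValidationError):
            build_reflection_set([[3, 0, 0]], [1.0], None,
                                 (20, 25, 30, 90, 90, 90), "P212121")

    def test_d_spacing_orthogonal(self, tmp_path):
        p = tmp_path / "r.hkl"
        p.write_text("1 0 0 5.0\n")
        rs = read_reflections(p, (10, 10, 10, 90, 90, 90), "P1")
        assert rs.d[0] == pytest.approx(10.0)

    def test_negative_f_rejected(self, tmp_path):
        p = tmp_path / "r.hkl"
        p.write_text("1 0 0 -5.0\n")
        with pytest.raises(ValidationError):
            read_reflections(p, (10, 10, 10, 90, 90, 90), "P1")

    def test_reduction_involutive(self, refl60):
        again = build_reflection_set(refl60.hkl, refl60.f, refl60.sigf,
                                     refl60.cell, refl60.space_group)
        assert again.n_reflections == refl60.n_reflections
        assert np.array_equal(np.sort(again.hkl, axis=0),
                              np.sort(refl60.hkl, axis=0))
        order = np.lexsort(again.hkl.T)
        order0 = np.lexsort(refl60.hkl.T)
        assert np.allclose(again.f[order], refl60.f[order0])

    def test_mmcif_refln_loop(self, tmp_path):
        cif = """\
data_r
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.F_meas_au
_refln.F_meas_sigma_au
1 0 0 5.0 0.5
0 1 0 4.0 0.4
"""
        p = tmp_path / "r.cif"
        p.write_text(cif)
        rs = read_reflections(p, (10, 10, 10, 90, 90, 90), "P1")
        assert rs.n_reflections == 2
        assert np.isfinite(rs.sigf).all()

    def test_write_read_round_trip(self, tmp_path, refl60):
        p = tmp_path / "r.hkl"
        iohub.write_reflections(refl60, p)
        back = read_reflections(p, refl60.cell, refl60.space_group)
        assert back.n_reflections == refl60.n_reflections


@pytest.mark.parametrize("symbol", ["P1", "P21", "P212121"])
def test_centric_epsilon_brute_force(symbol):
    """Centric flags and epsilon factors agree with an explicit loop over
    the group's rotation operators on small index ranges."""
    sg = get_space_group(symbol)
    ops = sg.operations()
    rots = [np.array(op.rot) // op.DEN for op in ops]
    rng = range(-4, 5)
    for h in rng:
        for k in rng:
            for l in rng:
                if (h, k, l) == (0, 0, 0):
                    continue
                hkl = np.array([h, k, l])
                images = [tuple(hkl @ R) for R in rots]
                brute_centric = tuple(-hkl) in images
                brute_eps = sum(im == tuple(hkl) for im in images)
                assert brute_eps >= 1
                assert ops.is_reflection_centric([h, k, l]) == brute_centric
                assert ops.epsilon_factor([h, k, l]) == brute_eps
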