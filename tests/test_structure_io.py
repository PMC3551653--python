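"""Structure reading, SYBYL typing, pseudo-ligands and fragment output."""

import numpy as np
import pytest

import fragvlib as fv
from fragvlib.fragment_extract import Fragment, FragmentLibrary
from fragvlib.structure_io import (EmptyLigandError, ParseError, read_mol2,
                                   write_complex)
from fragvlib.sybyl import ATOM_TYPE_SET

RECEPTOR_MOL2 = """@<TRIPOS>MOLECULE
rec
6 4 1 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
     1 C1     0.000  0.000  0.000 C.3    1 REC1   0.0
     2 N1     1.500  0.000  0.000 N.am   1 REC1   0.0
     3 C2     2.250  1.300  0.000 C.2    1 REC1   0.0
     4 H1     0.300  0.900  0.000 H      1 REC1   0.0
     5 O1     2.800  0.000  3.000 O.3    2 HOH2   0.0
     6 S1     3.700  1.300  1.200 S.3    1 REC1   0.0
@<TRIPOS>BOND
    1 1 2 1
    2 2 3 am
    3 1 4 1
    4 3 6 1
"""

LIGAND_MOL2 = """@<TRIPOS>MOLECULE
lig
3 2 1 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
     1 C1     1.000  0.500  2.800 C.ar   1 LIG1   0.0
     2 C2     2.400  0.500  2.800 C.ar   1 LIG1   0.0
     3 O1     3.200  1.600  2.900 O.2    1 LIG1   0.0
@<TRIPOS>BOND
    1 1 2 ar
    2 2 3 2
"""


@pytest.fixture
def complex_files(tmp_path):
    rec = tmp_path / "rec.mol2"
    lig = tmp_path / "lig.mol2"
    rec.write_text(RECEPTOR_MOL2)
    lig.write_text(LIGAND_MOL2)
    return rec, lig


class TestReadComplex:
    def test_roles_and_hydrogen_exclusion(self, complex_files):
        cx = fv.read_complex(*complex_files)
        # 4 heavy receptor atoms (H dropped, water dropped), 3 ligand atoms
        assert cx.role_counts() == {"receptor": 4, "ligand": 3, "water": 0}
        assert all(a.element != "H" for a in cx.atoms)
        # the bond to the dropped hydrogen disappeared with it
        assert len(cx.bonds) == 3 + 2

    def test_include_waters_keeps_typed_water(self, complex_files):
        cx = fv.read_complex(*complex_files, include_waters=True)
        waters = cx.water_atoms
        assert len(waters) == 1
        assert waters[0].sybyl_type == "O.3"

    def test_mol2_types_pass_through(self, complex_files):
        cx = fv.read_complex(*complex_files)
        assert cx.atoms[1].sybyl_type == "N.am"
        assert {a.sybyl_type for a in cx.atoms} <= ATOM_TYPE_SET

    def test_unknown_sybyl_type_is_parse_error(self, tmp_path):
        bad = RECEPTOR_MOL2.replace("C.3", "X.9")
        path = tmp_path / "bad.mol2"
        path.write_text(bad)
        lig = tmp_path / "lig.mol2"
        lig.write_text(LIGAND_MOL2)
        with pytest.raises(ParseError, match="unknown SYBYL type"):
            fv.read_complex(path, lig)

    def test_empty_ligand_instructs_pseudo_ligand(self, tmp_path):
        rec = tmp_path / "rec.mol2"
        rec.write_text(RECEPTOR_MOL2)
        empty = tmp_path / "empty.mol2"
        empty.write_text("@<TRIPOS>MOLECULE\nempty\n0 0 1 0 0\nSMALL\n"
                         "NO_CHARGES\n\n@<TRIPOS>ATOM\n@<TRIPOS>BOND\n")
        with pytest.raises(EmptyLigandError, match="pseudo-ligand"):
            fv.read_complex(rec, empty)


class TestPseudoLigand:
    def test_replaces_real_ligand(self, complex_files, tmp_path):
        cx = fv.read_complex(*complex_files)
        pseudo = tmp_path / "pseudo.mol2"
        pseudo.write_text(LIGAND_MOL2.replace("3 2 1", "3 2 1")
                          .replace("O.2", "N.3"))
        out = fv.inject_pseudo_ligand(cx, pseudo)
        assert len(out.ligand_atoms) == 3
        assert out.pseudo_ligand
        assert any(a.sybyl_type == "N.3" for a in out.ligand_atoms)

    def test_empty_pseudo_rejected(self, complex_files, tmp_path):
        cx = fv.read_complex(*complex_files)
        empty = tmp_path / "empty.mol2"
        empty.write_text("@<TRIPOS>MOLECULE\nempty\n0 0 1 0 0\nSMALL\n"
                         "NO_CHARGES\n\n@<TRIPOS>ATOM\n@<TRIPOS>BOND\n")
        with pytest.raises(EmptyLigandError):
            fv.inject_pseudo_ligand(cx, empty)


def _pdb_line(serial, name, resname, resseq, x, y, z, element, record="ATOM",
              altloc=" ", occ=1.0):
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} A"
            f"{resseq:>4}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:6.2f}  0.00"
            f"          {element:>2}")


PEPTIDE_ATOMS = [
    (1, " N  ", "ALA", 1, 0.000, 0.000, 0.000, "N"),
    (2, " CA ", "ALA", 1, 1.458, 0.000, 0.000, "C"),
    (3, " C  ", "ALA", 1, 2.009, 1.420, 0.000, "C"),
    (4, " O  ", "ALA", 1, 1.251, 2.390, 0.000, "O"),
    (6, " N  ", "GLY", 2, 3.330, 1.540, 0.000, "N"),
    (7, " CA ", "GLY", 2, 3.990, 2.840, 0.050, "C"),
    (8, " C  ", "GLY", 2, 5.500, 2.700, 0.100, "C"),
    (9, " O  ", "GLY", 2, 6.100, 1.620, 0.100, "O"),
]


@pytest.fixture
def pdb_receptor(tmp_path):
    lines = [_pdb_line(*row) for row in PEPTIDE_ATOMS]
    # alternate locations for ALA CB: B has the higher occupancy
    lines.append(_pdb_line(5, " CB ", "ALA", 1, 1.990, -0.770, -1.200, "C",
                           altloc="A", occ=0.30))
    lines.append(_pdb_line(5, " CB ", "ALA", 1, 2.090, -0.870, -1.100, "C",
                           altloc="B", occ=0.70))
    lines.append(_pdb_line(20, "ZN  ", "ZN", 90, 10.0, 10.0, 10.0, "Zn",
                           record="HETATM"))
    lines.append(_pdb_line(21, " O  ", "HOH", 99, 8.0, 0.0, 0.0, "O",
                           record="HETATM"))
    lines.append("END")
    path = tmp_path / "pep.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPdbTyping:
    def test_rule_table_and_bond_perception(self, pdb_receptor, tmp_path):
        lig = tmp_path / "lig.mol2"
        lig.write_text(LIGAND_MOL2)
        cx = fv.read_complex(pdb_receptor, lig)
        types = {(a.residue_tag, a.name): a.sybyl_type
                 for a in cx.receptor_atoms}
        assert types[("ALA1", "O")] == "O.2"       # backbone carbonyl oxygen
        assert types[("ALA1", "N")] == "N.am"
        assert types[("GLY2", "CA")] == "C.3"
        assert types[("ZN90", "ZN")] == "Zn"
        bonds = {frozenset((cx.atoms[b.a].name, cx.atoms[b.b].name)):
                 b.bond_type
                 for b in cx.bonds
                 if cx.atoms[b.a].role == "receptor"}
        assert bonds[frozenset(("C", "N"))] == "am"     # peptide bond
        assert bonds[frozenset(("C", "O"))] == "2"      # carbonyl

    def test_waters_dropped_by_default(self, pdb_receptor, tmp_path):
        lig = tmp_path / "lig.mol2"
        lig.write_text(LIGAND_MOL2)
        cx = fv.read_complex(pdb_receptor, lig)
        assert cx.role_counts()["water"] == 0
        cx_w = fv.read_complex(pdb_receptor, lig, include_waters=True)
        assert cx_w.role_counts()["water"] == 1

    def test_highest_occupancy_altloc_kept(self, pdb_receptor, tmp_path):
        lig = tmp_path / "lig.mol2"
        lig.write_text(LIGAND_MOL2)
        cx = fv.read_complex(pdb_receptor, lig)
        cb = [a for a in cx.receptor_atoms if a.name == "CB"]
        assert len(cb) == 1
        assert np.allclose(cb[0].coords, [2.090, -0.870, -1.100])


class TestRoundTrip:
    def test_mol2_round_trip_preserves_complex(self, small_complex, tmp_path):
        rec = tmp_path / "out_protein.mol2"
        lig = tmp_path / "out_ligand.mol2"
        write_complex(small_complex, rec, lig)
        back = fv.read_complex(rec, lig, complex_id=small_complex.complex_id)
        assert len(back.atoms) == len(small_complex.atoms)
        assert [a.sybyl_type for a in back.atoms] == \
            [a.sybyl_type for a in small_complex.atoms]
        assert len(back.bonds) == len(small_complex.bonds)
        assert np.allclose(back.coords, small_complex.coords, atol=1e-5)

    def test_water_round_trip(self, water_complex, tmp_path):
        rec = tmp_path / "w_protein.mol2"
        lig = tmp_path / "w_ligand.mol2"
        write_complex(water_complex, rec, lig)
        back = fv.read_complex(rec, lig, include_waters=True)
        assert back.role_counts() == water_complex.role_counts()


class TestWriteFragments:
    def _library(self, n):
        frags = []
        for k in range(n):
            frags.append(Fragment(
                atoms=[("C.3", np.array([0.1 + k, 0.2, 0.3])),
                       ("N.am", np.array([1.3 + k, 0.2, 0.3]))],
                bonds=[(0, 1, "1")], source_complex_id=f"cx{k}",
                match_rmsd=0.01 * k, match_index=k))
        return FragmentLibrary("target", frags)

    @pytest.mark.parametrize("fmt", ["mol2", "sdf"])
    def test_entries_and_manifest(self, tmp_path, fmt):
        rows = fv.write_fragments(self._library(3), tmp_path, format=fmt)
        assert len(rows) == 3
        assert (tmp_path / f"fragments.{fmt}").exists()
        manifest = (tmp_path / "manifest.tsv").read_text().splitlines()
        assert len(manifest) == 4  # header + 3 rows
        assert rows[1]["fragment_id"] == "cx1_match1"

    def test_empty_library(self, tmp_path):
        rows = fv.write_fragments(self._library(0), tmp_path)
        assert rows == []
        assert (tmp_path / "manifest.tsv").read_text().count("\n") == 1

    def test_fragment_round_trip_precision(self, tmp_path):
        fv.write_fragments(self._library(2), tmp_path)
        mols = read_mol2(tmp_path / "fragments.mol2")
        assert len(mols) == 2
        assert np.allclose(mols[0].coords, [[0.1, 0.2, 0.3], [1.3, 0.2, 0.3]],
                           atol=1e-4)
        assert mols[0].types == ["C.3", "N.am"]
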