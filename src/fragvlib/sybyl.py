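"""SYBYL atom- and bond-type vocabulary used to label interfacial graphs.

The vocabulary is closed: 41 atom types (Tripos MOL2 convention, element plus
hybridization/environment) and five covalent bond types, with the sentinel
label ``nc`` ("not connected") reserved for non-covalent interface edges.
Hydrogens have no type here and are excluded everywhere.
"""

from __future__ import annotations

ATOM_TYPES: tuple[str, ...] = (
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2",
    "S.3", "S.2", "S.O", "S.O2",
    "P.3",
    "F", "Cl", "Br", "I",
    "Li", "Na", "Mg", "Al", "Si", "K", "Ca",
    "Cr.th", "Cr.oh", "Mn", "Fe", "Co.oh", "Cu", "Se", "Mo", "Sn", "Zn",
)

ATOM_TYPE_SET = frozenset(ATOM_TYPES)

#: Covalent bond labels; "nc" is an interface-edge label, never a molecular bond.
COVALENT_BOND_TYPES: tuple[str, ...] = ("1", "2", "3", "am", "ar")
NC = "nc"

#: MOL2 atom types that denote particles we drop silently (hydrogens, dummies,
#: lone pairs) rather than reject.
_DROPPED_TYPE_PREFIXES = ("H", "Du", "LP")

WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"})


def element_of(sybyl_type: str) -> str:
    """Chemical element symbol of a SYBYL atom type (``N.am`` -> ``N``)."""
    return sybyl_type.split(".", 1)[0]


def is_dropped_type(sybyl_type: str) -> bool:
    """True for hydrogen/dummy/lone-pair MOL2 types that are silently removed."""
    base = sybyl_type.split(".", 1)[0]
    return base in ("H", "D") or sybyl_type.startswith(("Du", "LP"))


# ---------------------------------------------------------------------------
# PDB typing rules
# ---------------------------------------------------------------------------

def _backbone() -> dict[str, str]:
    return {"N": "N.am", "CA": "C.3", "C": "C.2", "O": "O.2", "OXT": "O.co2"}


def _residue(side: dict[str, str]) -> dict[str, str]:
    d = _backbone()
    d.update(side)
    return d


_AR = "C.ar"

#: (residue name, atom name) -> SYBYL type for the 20 standard amino acids.
#: Ring systems are typed aromatic (HIS, TRP ring nitrogens as N.ar).
AMINO_ACID_TYPES: dict[str, dict[str, str]] = {
    "ALA": _residue({"CB": "C.3"}),
    "ARG": _residue({"CB": "C.3", "CG": "C.3", "CD": "C.3", "NE": "N.pl3",
                     "CZ": "C.cat", "NH1": "N.pl3", "NH2": "N.pl3"}),
    "ASN": _residue({"CB": "C.3", "CG": "C.2", "OD1": "O.2", "ND2": "N.am"}),
    "ASP": _residue({"CB": "C.3", "CG": "C.2", "OD1": "O.co2", "OD2": "O.co2"}),
    "CYS": _residue({"CB": "C.3", "SG": "S.3"}),
    "GLN": _residue({"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.2",
                     "NE2": "N.am"}),
    "GLU": _residue({"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.co2",
                     "OE2": "O.co2"}),
    "GLY": _backbone(),
    "HIS": _residue({"CB": "C.3", "CG": _AR, "ND1": "N.ar", "CD2": _AR,
                     "CE1": _AR, "NE2": "N.ar"}),
    "ILE": _residue({"CB": "C.3", "CG1": "C.3", "CG2": "C.3", "CD1": "C.3"}),
    "LEU": _residue({"CB": "C.3", "CG": "C.3", "CD1": "C.3", "CD2": "C.3"}),
    "LYS": _residue({"CB": "C.3", "CG": "C.3", "CD": "C.3", "CE": "C.3",
                     "NZ": "N.4"}),
    "MET": _residue({"CB": "C.3", "CG": "C.3", "SD": "S.3", "CE": "C.3"}),
    "PHE": _residue({"CB": "C.3", "CG": _AR, "CD1": _AR, "CD2": _AR,
                     "CE1": _AR, "CE2": _AR, "CZ": _AR}),
    "PRO": _residue({"CB": "C.3", "CG": "C.3", "CD": "C.3"}),
    "SER": _residue({"CB": "C.3", "OG": "O.3"}),
    "THR": _residue({"CB": "C.3", "OG1": "O.3", "CG2": "C.3"}),
    "TRP": _residue({"CB": "C.3", "CG": _AR, "CD1": _AR, "NE1": "N.ar",
                     "CD2": _AR, "CE2": _AR, "CE3": _AR, "CZ2": _AR,
                     "CZ3": _AR, "CH2": _AR}),
    "TYR": _residue({"CB": "C.3", "CG": _AR, "CD1": _AR, "CD2": _AR,
                     "CE1": _AR, "CE2": _AR, "CZ": _AR, "OH": "O.3"}),
    "VAL": _residue({"CB": "C.3", "CG1": "C.3", "CG2": "C.3"}),
}

#: Element -> SYBYL type fallback for atoms outside the amino-acid rule table
#: (HETATM ligand/cofactor atoms, metal ions, nonstandard residues).
ELEMENT_FALLBACK: dict[str, str] = {
    "C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3",
    "F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
    "Li": "Li", "Na": "Na", "Mg": "Mg", "Al": "Al", "Si": "Si",
    "K": "K", "Ca": "Ca", "Mn": "Mn", "Fe": "Fe", "Cu": "Cu",
    "Se": "Se", "Mo": "Mo", "Sn": "Sn", "Zn": "Zn",
    "Co": "Co.oh", "Cr": "Cr.oh",
}

METAL_ELEMENTS = frozenset({
    "Li", "Na", "Mg", "Al", "K", "Ca", "Cr", "Mn", "Fe", "Co", "Cu",
    "Mo", "Sn", "Zn",
})

#: Single-bond covalent radii in Angstrom (Cordero et al. consensus values),
#: used only for PDB bond perception.
COVALENT_RADII: dict[str, float] = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
    "Li": 1.28, "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11,
    "K": 2.03, "Ca": 1.76, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32,
    "Co": 1.26, "Cu": 1.32, "Mo": 1.54, "Sn": 1.39, "Zn": 1.22,
}

#: Slack added to the covalent-radius sum in the PDB distance bonding rule.
BOND_TOLERANCE = 0.45
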