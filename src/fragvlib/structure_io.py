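"""Reading, typing and writing of ligand-receptor complexes.

A complex is a flat list of typed heavy atoms (receptor / ligand / water
roles) plus undirected covalent bonds. MOL2 is the authoritative format for
ligands (it carries SYBYL types and bonds); PDB receptors are typed by a
rule table and bonded by a covalent-radius distance rule. Hydrogens are
excluded throughout: the labeling vocabulary has no hydrogen type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .sybyl import (
    AMINO_ACID_TYPES,
    ATOM_TYPE_SET,
    BOND_TOLERANCE,
    COVALENT_BOND_TYPES,
    COVALENT_RADII,
    ELEMENT_FALLBACK,
    METAL_ELEMENTS,
    WATER_RESIDUE_NAMES,
    element_of,
    is_dropped_type,
)

logger = logging.getLogger("fragvlib.structure_io")

ROLES = ("receptor", "ligand", "water")


class ParseError(ValueError):
    """A structure file could not be parsed; the message names the line."""


class EmptyLigandError(ValueError):
    """The complex has no ligand atoms; a pseudo-ligand is required."""


@dataclass
class Atom:
    """One heavy atom of a complex.

    ``id`` is the 0-based position in the owning complex's atom list;
    ``sybyl_type`` is one of the 41 vocabulary types (or None before typing);
    ``role`` partitions the complex into receptor / ligand / water sides.
    """

    id: int
    element: str
    sybyl_type: str | None
    coords: np.ndarray
    role: str
    residue_tag: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.id}: coords must be 3 finite numbers")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.id}: unknown role {self.role!r}")
        if self.sybyl_type is not None and self.sybyl_type not in ATOM_TYPE_SET:
            raise ValueError(
                f"atom {self.id}: unknown SYBYL type {self.sybyl_type!r}")


@dataclass(frozen=True)
class Bond:
    """Undirected covalent bond, order-normalized so a < b."""

    a: int
    b: int
    bond_type: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-bond on atom {self.a}")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)
        if self.bond_type not in COVALENT_BOND_TYPES:
            raise ValueError(f"bond type {self.bond_type!r} is not covalent")


@dataclass
class MolecularComplex:
    """Typed atoms + covalent bonds of one receptor-ligand pair."""

    complex_id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source_path: str = ""
    pseudo_ligand: bool = False

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms):
            if atom.id != i:
                raise ValueError("atom ids must equal list positions")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond ({bond.a},{bond.b}) references missing atom")
            key = (bond.a, bond.b)
            if key in seen:
                raise ValueError(f"duplicate bond ({bond.a},{bond.b})")
            seen.add(key)

    # -- convenience views ---------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atoms_with_role(self, role: str) -> list[Atom]:
        return [a for a in self.atoms if a.role == role]

    @property
    def receptor_atoms(self) -> list[Atom]:
        return self.atoms_with_role("receptor")

    @property
    def ligand_atoms(self) -> list[Atom]:
        return self.atoms_with_role("ligand")

    @property
    def water_atoms(self) -> list[Atom]:
        return self.atoms_with_role("water")

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for a in self.atoms:
            counts[a.role] += 1
        return counts

    def neighbors(self) -> dict[int, list[tuple[int, str]]]:
        """Covalent adjacency: atom id -> [(neighbor id, bond type), ...]."""
        adj: dict[int, list[tuple[int, str]]] = {a.id: [] for a in self.atoms}
        for b in self.bonds:
            adj[b.a].append((b.b, b.bond_type))
            adj[b.b].append((b.a, b.bond_type))
        return adj

    def validate(self) -> None:
        """Enforce the complex invariants (roles present, coords distinct)."""
        counts = self.role_counts()
        if counts["receptor"] == 0:
            raise ValueError(f"{self.complex_id}: no receptor atoms")
        if counts["ligand"] == 0:
            raise EmptyLigandError(
                f"{self.complex_id}: no ligand atoms; supply a bound ligand "
                "or use inject_pseudo_ligand / --pseudo-ligand to delineate "
                "the binding pocket")
        coords = self.coords
        if len(coords) > 1:
            tree = cKDTree(coords)
            pairs = tree.query_pairs(1e-6)
            if pairs:
                i, j = sorted(pairs)[0]
                raise ValueError(
                    f"{self.complex_id}: atoms {i} and {j} share coordinates")


# ---------------------------------------------------------------------------
# MOL2 parsing
# ---------------------------------------------------------------------------

@dataclass
class Mol2Molecule:
    """One ``@<TRIPOS>MOLECULE`` block: raw atoms, bonds, substructure names."""

    name: str
    atom_names: list[str] = field(default_factory=list)
    types: list[str] = field(default_factory=list)
    coords: list[np.ndarray] = field(default_factory=list)
    subst_names: list[str] = field(default_factory=list)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)  # 0-based


def read_mol2(path: str | Path) -> list[Mol2Molecule]:
    """Parse a Tripos MOL2 file into molecule blocks.

    Hydrogens, dummy atoms and lone pairs are dropped silently (with their
    bonds); any other atom type outside the vocabulary raises :class:`ParseError`
    naming the offending line. Multiple MOLECULE blocks are supported.
    """
    path = Path(path)
    molecules: list[Mol2Molecule] = []
    section = None
    mol: Mol2Molecule | None = None
    mol_header_lines = 0
    # per-molecule: original 1-based atom id -> new 0-based id or None (dropped)
    id_map: dict[int, int | None] = {}

    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("#") or (not stripped and section != "MOLECULE"):
                continue
            if stripped.startswith("@<TRIPOS>"):
                section = stripped[len("@<TRIPOS>"):].upper()
                if section == "MOLECULE":
                    mol = Mol2Molecule(name="")
                    molecules.append(mol)
                    id_map = {}
                    mol_header_lines = 0
                continue
            if section == "MOLECULE":
                if mol is None:
                    raise ParseError(f"{path}:{lineno}: data before MOLECULE record")
                mol_header_lines += 1
                if mol_header_lines == 1:
                    mol.name = stripped or path.stem
                continue
            if section == "ATOM":
                if mol is None:
                    raise ParseError(f"{path}:{lineno}: ATOM before MOLECULE")
                fields = stripped.split()
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: malformed ATOM record {stripped!r}")
                try:
                    orig_id = int(fields[0])
                    xyz = np.array([float(fields[2]), float(fields[3]),
                                    float(fields[4])])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed ATOM record: {exc}") from None
                sybyl = fields[5]
                if is_dropped_type(sybyl):
                    id_map[orig_id] = None
                    continue
                if sybyl not in ATOM_TYPE_SET:
                    raise ParseError(
                        f"{path}:{lineno}: unknown SYBYL type {sybyl!r}")
                if not np.all(np.isfinite(xyz)):
                    raise ParseError(f"{path}:{lineno}: non-finite coordinates")
                id_map[orig_id] = len(mol.types)
                mol.atom_names.append(fields[1])
                mol.types.append(sybyl)
                mol.coords.append(xyz)
                mol.subst_names.append(fields[7] if len(fields) > 7 else "")
                continue
            if section == "BOND":
                if mol is None:
                    raise ParseError(f"{path}:{lineno}: BOND before MOLECULE")
                fields = stripped.split()
                if len(fields) < 4:
                    raise ParseError(
                        f"{path}:{lineno}: malformed BOND record {stripped!r}")
                try:
                    a, b = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed BOND record {stripped!r}"
                    ) from None
                btype = fields[3]
                na, nb = id_map.get(a), id_map.get(b)
                if na is None or nb is None:
                    continue  # bond to a dropped atom (hydrogen etc.)
                if btype in ("un", "du"):
                    btype = "1"
                if btype not in COVALENT_BOND_TYPES:
                    raise ParseError(
                        f"{path}:{lineno}: unknown bond type {btype!r}")
                mol.bonds.append((min(na, nb), max(na, nb), btype))
                continue
            # other sections (SUBSTRUCTURE, CRYSIN, ...) are ignored
    if not molecules:
        raise ParseError(f"{path}: no @<TRIPOS>MOLECULE record found")
    return molecules


def _is_water_subst(subst_name: str) -> bool:
    base = subst_name.strip().upper()
    return any(base.startswith(w) for w in WATER_RESIDUE_NAMES)


def _atoms_from_mol2(mol: Mol2Molecule, default_role: str,
                     start_id: int) -> tuple[list[Atom], list[Bond]]:
    atoms = []
    for i, sybyl in enumerate(mol.types):
        role = "water" if _is_water_subst(mol.subst_names[i]) else default_role
        atoms.append(Atom(
            id=start_id + i,
            element=element_of(sybyl),
            sybyl_type=sybyl,
            coords=mol.coords[i],
            role=role,
            residue_tag=mol.subst_names[i] or mol.name,
            name=mol.atom_names[i],
        ))
    bonds = [Bond(start_id + a, start_id + b, t) for a, b, t in mol.bonds]
    return atoms, bonds


# ---------------------------------------------------------------------------
# PDB parsing (via gemmi)
# ---------------------------------------------------------------------------

def _read_pdb_atoms(path: Path, default_role: str) -> list[Atom]:
    """ATOM/HETATM records as untyped heavy atoms; highest-occupancy altloc."""
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    if len(structure) == 0:
        raise ParseError(f"{path}: no models found")
    model = structure[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            is_water = resname in WATER_RESIDUE_NAMES
            # keep the highest-occupancy alternate location per atom name
            best: dict[str, object] = {}
            for atom in residue:
                el = atom.element.name
                if el in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:  # type: ignore[union-attr]
                    best[atom.name] = atom
            for name in sorted(best):
                atom = best[name]
                tag = f"{resname}{residue.seqid.num}"
                atoms.append(Atom(
                    id=len(atoms),
                    element=atom.element.name,
                    sybyl_type=None,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    role="water" if is_water else default_role,
                    residue_tag=tag,
                    name=name,
                ))
    return atoms


def perceive_bonds(atoms: Sequence[Atom]) -> list[Bond]:
    """Distance-rule covalent bonds: d < r_cov(a) + r_cov(b) + 0.45 Å.

    Waters and metals form no covalent bonds (metal contacts are
    coordination, not covalence); bond order defaults to single, refined to
    amide/aromatic/double after typing by :func:`_refine_bond_orders`.
    """
    idx = [a.id for a in atoms
           if a.role != "water" and a.element not in METAL_ELEMENTS
           and a.element in COVALENT_RADII]
    if len(idx) < 2:
        return []
    by_id = {a.id: a for a in atoms}
    coords = np.array([by_id[i].coords for i in idx])
    max_reach = 2 * max(COVALENT_RADII[by_id[i].element] for i in idx) + BOND_TOLERANCE
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(max_reach)):
        ai, aj = by_id[idx[i]], by_id[idx[j]]
        d = float(np.linalg.norm(ai.coords - aj.coords))
        limit = COVALENT_RADII[ai.element] + COVALENT_RADII[aj.element] + BOND_TOLERANCE
        if 0.4 < d < limit:
            bonds.append(Bond(ai.id, aj.id, "1"))
    return bonds


def _refine_bond_orders(atoms: Sequence[Atom], bonds: list[Bond]) -> list[Bond]:
    """Rule-typed bond orders for distance-perceived bonds.

    Aromatic-aromatic pairs in one residue -> "ar"; amide N to carbonyl C
    -> "am" (covers peptide bonds); carbonyl/carboxylate C-O -> "2";
    everything else stays single.
    """
    by_id = {a.id: a for a in atoms}
    out = []
    for bond in bonds:
        a, b = by_id[bond.a], by_id[bond.b]
        ta, tb = a.sybyl_type or "", b.sybyl_type or ""
        btype = "1"
        if ta.endswith(".ar") and tb.endswith(".ar") and a.residue_tag == b.residue_tag:
            btype = "ar"
        elif {ta, tb} == {"N.am", "C.2"}:
            btype = "am"
        elif ("C.2" in (ta, tb)) and (("O.2" in (ta, tb)) or ("O.co2" in (ta, tb))):
            btype = "2"
        out.append(Bond(bond.a, bond.b, btype))
    return out


# ---------------------------------------------------------------------------
# Typing
# ---------------------------------------------------------------------------

def assign_sybyl_types(complex_: MolecularComplex) -> MolecularComplex:
    """Ensure every atom carries a vocabulary SYBYL type.

    MOL2-supplied types pass through unchanged. Untyped (PDB-derived) atoms
    are typed by the (residue, atom-name) rule table for the 20 standard
    amino acids, by the element map for metals/waters/other residues. Atoms
    whose element has no vocabulary type are dropped with a logged warning
    (atom ids are then recompacted).
    """
    typed: list[Atom] = []
    dropped: list[int] = []
    for atom in complex_.atoms:
        if atom.sybyl_type is not None:
            typed.append(atom)
            continue
        if atom.role == "water":
            new_type = "O.3" if atom.element == "O" else None
        else:
            resname = atom.residue_tag.rstrip("0123456789-")
            table = AMINO_ACID_TYPES.get(resname)
            new_type = table.get(atom.name) if table else None
            if new_type is None:
                new_type = ELEMENT_FALLBACK.get(atom.element)
                if table is None and new_type is not None:
                    logger.debug("%s: element-level type %s for %s/%s",
                                 complex_.complex_id, new_type,
                                 atom.residue_tag, atom.name)
        if new_type is None:
            logger.warning("%s: dropping atom %d (%s %s/%s): element outside "
                           "the type vocabulary", complex_.complex_id, atom.id,
                           atom.element, atom.residue_tag, atom.name)
            dropped.append(atom.id)
            continue
        typed.append(replace(atom, sybyl_type=new_type))
    if dropped:
        drop = set(dropped)
        remap = {}
        for new_id, atom in enumerate(typed):
            remap[atom.id] = new_id
            atom.id = new_id
        bonds = [Bond(remap[b.a], remap[b.b], b.bond_type)
                 for b in complex_.bonds if b.a not in drop and b.b not in drop]
    else:
        bonds = complex_.bonds
    return MolecularComplex(complex_.complex_id, typed, bonds,
                            complex_.source_path, complex_.pseudo_ligand)


# ---------------------------------------------------------------------------
# Complex assembly
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        return "mol2"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    with path.open() as handle:
        head = handle.read(4096)
    if "@<TRIPOS>" in head:
        return "mol2"
    if any(head.startswith(p) or f"\n{p}" in head
           for p in ("ATOM", "HETATM", "HEADER", "REMARK", "CRYST1")):
        return "pdb"
    raise ParseError(f"{path}: cannot detect format (expected mol2 or PDB)")


def _read_side(path: Path, default_role: str,
               start_id: int) -> tuple[list[Atom], list[Bond]]:
    fmt = _detect_format(path)
    if fmt == "mol2":
        mol = read_mol2(path)[0]
        return _atoms_from_mol2(mol, default_role, start_id)
    atoms = _read_pdb_atoms(path, default_role)
    bonds = perceive_bonds(atoms)
    for atom in atoms:
        atom.id += start_id
    bonds = [Bond(b.a + start_id, b.b + start_id, b.bond_type) for b in bonds]
    return atoms, bonds


def read_complex(receptor_path: str | Path, ligand_path: str | Path,
                 include_waters: bool = False,
                 complex_id: str | None = None) -> MolecularComplex:
    """Load a receptor file + ligand file into one typed complex.

    Receptor-file atoms get role receptor (or water by residue name); ligand
    file atoms get role ligand. Waters are dropped unless ``include_waters``.
    Hydrogens are always dropped. PDB receptors are typed and bonded by rule;
    PDB-perceived bond orders are refined after typing.
    """
    receptor_path, ligand_path = Path(receptor_path), Path(ligand_path)
    receptor_is_pdb = _detect_format(receptor_path) == "pdb"
    rec_atoms, rec_bonds = _read_side(receptor_path, "receptor", 0)
    lig_atoms, lig_bonds = _read_side(ligand_path, "ligand", len(rec_atoms))
    atoms = rec_atoms + lig_atoms
    bonds = rec_bonds + lig_bonds
    if not include_waters:
        atoms, bonds = _drop_atoms(atoms, bonds, {a.id for a in atoms
                                                  if a.role == "water"})
    if complex_id is None:
        complex_id = _common_stem(receptor_path, ligand_path)
    cx = MolecularComplex(complex_id, atoms, bonds,
                          source_path=str(receptor_path))
    cx = assign_sybyl_types(cx)
    if receptor_is_pdb:
        cx.bonds = _refine_bond_orders(cx.atoms, cx.bonds)
    cx.validate()
    return cx


def _common_stem(receptor_path: Path, ligand_path: Path) -> str:
    stem = receptor_path.stem
    for suffix in ("_protein", "_receptor", "_pocket"):
        if stem.endswith(suffix):
            return stem[: -len(suffix)]
    return stem


def _drop_atoms(atoms: list[Atom], bonds: list[Bond],
                drop: set[int]) -> tuple[list[Atom], list[Bond]]:
    kept = [a for a in atoms if a.id not in drop]
    remap = {}
    for new_id, atom in enumerate(kept):
        remap[atom.id] = new_id
        atom.id = new_id
    new_bonds = [Bond(remap[b.a], remap[b.b], b.bond_type)
                 for b in bonds if b.a not in drop and b.b not in drop]
    return kept, new_bonds


def inject_pseudo_ligand(complex_: MolecularComplex,
                         pseudo_path: str | Path) -> MolecularComplex:
    """Replace the complex's ligand with a user-designed pseudo-ligand.

    The pseudo-ligand exists only to delineate the binding pocket; the
    resulting complex is flagged so downstream fragments are not mistaken
    for a real bound ligand.
    """
    mol = read_mol2(Path(pseudo_path))[0]
    if not mol.types:
        raise EmptyLigandError(f"{pseudo_path}: pseudo-ligand has no heavy atoms")
    atoms = [a for a in complex_.atoms if a.role != "ligand"]
    bonds = [b for b in complex_.bonds]
    keep_ids = {a.id for a in atoms}
    atoms, bonds = _drop_atoms(list(atoms),
                               [b for b in bonds
                                if b.a in keep_ids and b.b in keep_ids],
                               set())
    pseudo_atoms, pseudo_bonds = _atoms_from_mol2(mol, "ligand", len(atoms))
    cx = MolecularComplex(complex_.complex_id, atoms + pseudo_atoms,
                          bonds + pseudo_bonds, complex_.source_path,
                          pseudo_ligand=True)
    cx.validate()
    return cx


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def format_mol2_block(name: str, types: Sequence[str],
                      coords: np.ndarray,
                      bonds: Iterable[tuple[int, int, str]],
                      subst_names: Sequence[str] | None = None,
                      atom_names: Sequence[str] | None = None) -> str:
    """Render one MOL2 MOLECULE block (coordinates at 1e-6 Å precision)."""
    coords = np.asarray(coords, dtype=float)
    bonds = list(bonds)
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{len(types)} {len(bonds)} 1 0 0", "SMALL", "NO_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i, sybyl in enumerate(types):
        aname = (atom_names[i] if atom_names else None) or \
            f"{element_of(sybyl)}{i + 1}"
        subst = (subst_names[i] if subst_names else None) or "MOL1"
        x, y, z = coords[i]
        lines.append(f"{i + 1:>7} {aname:<8} {x:>13.6f} {y:>13.6f} {z:>13.6f} "
                     f"{sybyl:<7} 1 {subst:<8} 0.0000")
    lines.append("@<TRIPOS>BOND")
    for k, (a, b, btype) in enumerate(bonds, start=1):
        lines.append(f"{k:>6} {a + 1:>5} {b + 1:>5} {btype:>4}")
    lines.append("")
    return "\n".join(lines)


def write_complex(complex_: MolecularComplex, receptor_path: str | Path,
                  ligand_path: str | Path) -> None:
    """Write a complex as a receptor mol2 + ligand mol2 pair (waters stay
    with the receptor file, tagged HOH so they round-trip as waters)."""
    def _side(atom_filter) -> tuple[list[Atom], list[tuple[int, int, str]]]:
        atoms = [a for a in complex_.atoms if atom_filter(a)]
        local = {a.id: i for i, a in enumerate(atoms)}
        bonds = [(local[b.a], local[b.b], b.bond_type) for b in complex_.bonds
                 if b.a in local and b.b in local]
        return atoms, bonds

    for path, atom_filter in (
            (Path(receptor_path), lambda a: a.role in ("receptor", "water")),
            (Path(ligand_path), lambda a: a.role == "ligand")):
        atoms, bonds = _side(atom_filter)
        substs = ["HOH1" if a.role == "water" else (a.residue_tag or "MOL1")
                  for a in atoms]
        block = format_mol2_block(
            complex_.complex_id, [a.sybyl_type or "C.3" for a in atoms],
            np.array([a.coords for a in atoms]).reshape(-1, 3), bonds,
            subst_names=substs, atom_names=[a.name or "" for a in atoms])
        path.write_text(block)


def _format_sdf_entry(name: str, types: Sequence[str], coords: np.ndarray,
                      bonds: list[tuple[int, int, str]]) -> str:
    order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 4}
    lines = [name, "  fragvlib", "",
             f"{len(types):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000"]
    for i, sybyl in enumerate(types):
        x, y, z = coords[i]
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {element_of(sybyl):<3}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, btype in bonds:
        lines.append(f"{a + 1:>3}{b + 1:>3}{order[btype]:>3}  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_fragments(library, out_dir: str | Path, format: str = "mol2"):
    """Write a fragment library plus its TSV manifest.

    One multi-entry file (``fragments.mol2`` or ``fragments.sdf``) with each
    entry named ``<source_complex_id>_match<k>``; coordinates are in the
    target receptor's frame. Returns the manifest rows as a list of dicts.
    """
    if format not in ("mol2", "sdf"):
        raise ValueError(f"unsupported fragment format {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    rows = []
    for frag in library.fragments:
        name = f"{frag.source_complex_id}_match{frag.match_index}"
        coords = np.array([c for _, c in frag.atoms], dtype=float).reshape(-1, 3)
        types = [t for t, _ in frag.atoms]
        if format == "mol2":
            entries.append(format_mol2_block(name, types, coords, frag.bonds))
        else:
            entries.append(_format_sdf_entry(name, types, coords, frag.bonds))
        rows.append({
            "fragment_id": name,
            "source_complex": frag.source_complex_id,
            "match_index": frag.match_index,
            "match_rmsd": f"{frag.match_rmsd:.6f}",
            "n_atoms": len(frag.atoms),
            "n_components": frag.n_components,
            "flagged_duplicate": int(frag.flagged_duplicate),
        })
    frag_path = out_dir / f"fragments.{format}"
    frag_path.write_text("\n".join(entries) + ("\n" if entries else ""))
    manifest_path = out_dir / "manifest.tsv"
    header = ["fragment_id", "source_complex", "match_index", "match_rmsd",
              "n_atoms", "n_components", "flagged_duplicate"]
    with manifest_path.open("w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(row[h]) for h in header) + "\n")
    return rows
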