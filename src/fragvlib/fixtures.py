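"""Synthetic complexes and planted-pocket databases.

Real pocket searches run over curated complex databases (PDBbind-style
layouts); these generators emulate just enough of that world for every
pipeline stage to be exercised without downloads: a receptor as a jittered
lattice chain of typed heavy atoms, a small ligand chain placed so a chosen
fraction of its atoms sits within interaction distance, optional bridging
waters, and decoy databases into which one complex's binding pocket is
planted under a known rigid transform (optionally with coordinate noise or
label mutations) so that matcher recovery and specificity have a ground
truth. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .interface_graph import InterfaceGraph, build_interface_graph
from .structure_io import Atom, Bond, MolecularComplex, write_complex
from .sybyl import NC

#: Reduced label alphabet used by default: keeps match multiplicity
#: interpretable in tests while spanning the common chemistries.
DEFAULT_ALPHABET: tuple[str, ...] = (
    "C.3", "C.2", "C.ar", "N.3", "N.am", "N.ar", "O.3", "O.2", "S.3", "P.3")

_LATTICE_SPACING = 1.5   # Å between chain neighbors (bond-ish)
_LIGAND_SPACING = 1.4
_CONTACT_OFFSET = 3.0    # Å from the anchor receptor atom to the ligand


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex."""

    n_receptor_atoms: int = 24
    n_ligand_atoms: int = 4
    label_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    contact_fraction: float = 0.75
    noise_sd: float = 0.25
    n_waters: int = 0
    cutoff: float = 5.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_atoms < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if not 0 <= self.contact_fraction <= 1:
            raise ValueError("contact_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _snake_lattice(n: int) -> np.ndarray:
    """First n points of a boustrophedon walk over a cubic lattice, so
    consecutive points are always one lattice spacing apart."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for k in range(side):
        for j in range(side):
            row = range(side) if (j + k * side) % 2 == 0 else range(side - 1, -1, -1)
            for i in row:
                pts.append((i, j, k))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * _LATTICE_SPACING
    return np.array(pts, dtype=float) * _LATTICE_SPACING


def make_complex(spec: FixtureSpec) -> MolecularComplex:
    """Build one synthetic complex from a spec; deterministic given its seed.

    The receptor is a chain over a jittered lattice with single/amide bonds;
    the ligand is a short chain whose first ``ceil(contact_fraction * n)``
    atoms are guaranteed within the cutoff of some receptor atom and, for
    contact_fraction 0, entirely beyond it. Raises if the construction
    cannot satisfy the requested contact fraction.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 313])
    rec = _snake_lattice(spec.n_receptor_atoms)
    rec = rec + rng.normal(0, spec.noise_sd / np.sqrt(3), rec.shape)
    rec_labels = rng.choice(spec.label_alphabet, spec.n_receptor_atoms)

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for i in range(spec.n_receptor_atoms):
        atoms.append(Atom(i, rec_labels[i].split(".")[0], str(rec_labels[i]),
                          rec[i], "receptor", residue_tag=f"REC{i + 1}"))
        if i:
            btype = "am" if rng.uniform() < 0.15 else "1"
            bonds.append(Bond(i - 1, i, btype))

    # ligand placement: a chain running under the receptor's bottom face,
    # one contact atom per ~1.4 Å of face, at the contact offset below it
    centroid = rec.mean(axis=0)
    z_min = rec[:, 2].min()
    bottom = rec[rec[:, 2] <= z_min + 0.8]
    x0 = bottom[:, 0].min()
    yc = float(np.median(bottom[:, 1]))

    n_contact = int(np.ceil(spec.contact_fraction * spec.n_ligand_atoms))
    lig_pts = []
    if n_contact == 0:
        radius = np.max(np.linalg.norm(rec - centroid, axis=1))
        start = centroid + np.array([0.0, 0.0, -(radius + spec.cutoff + 8.0)])
        for i in range(spec.n_ligand_atoms):
            lig_pts.append(start + np.array([_LIGAND_SPACING * i, 0.0, 0.0]))
    else:
        for i in range(n_contact):
            lig_pts.append(np.array([x0 + _LIGAND_SPACING * i, yc,
                                     z_min - _CONTACT_OFFSET])
                           + rng.normal(0, 0.05, 3))
        x_last = lig_pts[-1][0]
        z_far = z_min - spec.cutoff - 1.5
        for i in range(spec.n_ligand_atoms - n_contact):
            lig_pts.append(np.array([x_last, yc,
                                     z_far - _LIGAND_SPACING * (i + 1)]))
    lig = np.array(lig_pts).reshape(-1, 3)
    lig_labels = rng.choice(spec.label_alphabet, spec.n_ligand_atoms)

    base = spec.n_receptor_atoms
    for i in range(spec.n_ligand_atoms):
        atoms.append(Atom(base + i, lig_labels[i].split(".")[0],
                          str(lig_labels[i]), lig[i], "ligand",
                          residue_tag="LIG1"))
        if i:
            bonds.append(Bond(base + i - 1, base + i,
                              "2" if rng.uniform() < 0.2 else "1"))

    if spec.n_waters:
        face_point = np.array([x0, yc, z_min])
        mid = (face_point + lig[0]) / 2 if len(lig) else face_point
        base_w = base + spec.n_ligand_atoms
        for i in range(spec.n_waters):
            pos = mid + rng.normal(0, 0.8, 3) + np.array([2.0 * i, 0.0, 0.0])
            atoms.append(Atom(base_w + i, "O", "O.3", pos, "water",
                              residue_tag=f"HOH{i + 1}"))

    cx = MolecularComplex(f"syn{spec.seed}", atoms, bonds,
                          source_path="<synthetic>")
    _check_contacts(cx, spec, n_contact)
    return cx


def _check_contacts(cx: MolecularComplex, spec: FixtureSpec,
                    n_contact: int) -> None:
    rec = np.array([a.coords for a in cx.receptor_atoms])
    lig = np.array([a.coords for a in cx.ligand_atoms])
    dmin = np.linalg.norm(lig[:, None, :] - rec[None, :, :], axis=2).min(axis=1)
    within = int((dmin <= spec.cutoff).sum())
    if n_contact == 0 and within > 0:
        raise ValueError("contact_fraction 0 infeasible: ligand touches receptor")
    if within < n_contact:
        raise ValueError(
            f"requested {n_contact} contact atoms but only {within} lie "
            f"within {spec.cutoff} Å; adjust the fixture spec")


def random_rigid_transform(rng: np.random.Generator,
                           translation_scale: float = 20.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation (QR-based) + translation."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-translation_scale, translation_scale, 3)
    return q, t


@dataclass
class PlantedGroundTruth:
    """What was planted where: the decoy hosting the pocket, the rigid
    transform applied, and the donor-atom -> planted-atom id mapping."""

    planted_complex_id: str
    rotation: np.ndarray
    translation: np.ndarray
    donor_to_planted: dict[int, int]
    pocket_receptor_ids: tuple[int, ...] = ()
    mutated_planted_ids: tuple[int, ...] = ()


def plant_pocket(donor: MolecularComplex,
                 decoys: list[MolecularComplex],
                 transform_seed: int = 0,
                 coord_noise: float = 0.0,
                 label_mutations: int = 0,
                 cutoff: float = 5.8,
                 epsilon: float = 0.01,
                 out_dir: str | Path | None = None,
                 ) -> tuple[list[MolecularComplex], PlantedGroundTruth]:
    """Embed the donor's binding pocket into one decoy under a random rigid
    transform; return the database (decoys + planted entry) and ground truth.

    The planted material is the donor's interfacial receptor shell with its
    covalent neighbors (as extra receptor atoms) plus the full donor ligand,
    placed far enough from the host decoy's own atoms that no spurious
    contacts arise. ``coord_noise`` is the RMS magnitude of an isotropic
    Gaussian displacement per planted atom; ``label_mutations`` flips that
    many planted interfacial receptor labels to a different alphabet letter.
    If ``out_dir`` is given, a PDBbind-style directory plus a ground-truth
    TSV is written.
    """
    ig = build_interface_graph(donor, cutoff=cutoff, epsilon=epsilon)
    if ig.n_nodes == 0:
        raise ValueError("donor has an empty interface; nothing to plant")
    rng = np.random.default_rng([int(transform_seed) % (2**31), 7177])

    pocket_receptor = ig.receptor_nodes  # interfacial shell + covalent padding
    ligand_ids = [a.id for a in donor.ligand_atoms]
    planted_src = pocket_receptor + ligand_ids

    rotation, translation = random_rigid_transform(rng)
    host_idx = int(rng.integers(len(decoys)))
    host = decoys[host_idx]
    host_coords = host.coords
    host_centroid = host_coords.mean(axis=0)
    host_radius = np.max(np.linalg.norm(host_coords - host_centroid, axis=1))

    src_coords = np.array([donor.atoms[i].coords for i in planted_src])
    moved = (rotation @ src_coords.T).T + translation
    # shift the planted pocket clear of the host (>= 15 Å separation)
    moved_centroid = moved.mean(axis=0)
    moved_radius = np.max(np.linalg.norm(moved - moved_centroid, axis=1))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    shift = (host_centroid + direction * (host_radius + moved_radius + 15.0)
             - moved_centroid)
    moved = moved + shift
    translation = translation + shift
    if coord_noise > 0:
        moved = moved + rng.normal(0, coord_noise / np.sqrt(3), moved.shape)

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for atom in host.atoms:
        atoms.append(Atom(len(atoms), atom.element, atom.sybyl_type,
                          atom.coords.copy(), atom.role, atom.residue_tag,
                          atom.name))
    for bond in host.bonds:
        bonds.append(bond)

    donor_to_planted: dict[int, int] = {}
    for k, src_id in enumerate(planted_src):
        src = donor.atoms[src_id]
        role = "receptor" if src_id in set(pocket_receptor) else "ligand"
        donor_to_planted[src_id] = len(atoms)
        atoms.append(Atom(len(atoms), src.element, src.sybyl_type, moved[k],
                          role, residue_tag=f"PLT{k + 1}", name=src.name))
    planted_set = set(planted_src)
    for bond in donor.bonds:
        if bond.a in planted_set and bond.b in planted_set:
            bonds.append(Bond(donor_to_planted[bond.a],
                              donor_to_planted[bond.b], bond.bond_type))

    mutated: list[int] = []
    if label_mutations:
        alphabet = sorted({a.sybyl_type for a in donor.atoms if a.sybyl_type})
        interf = [donor_to_planted[v] for v in ig.interfacial_receptor_nodes]
        picks = rng.choice(len(interf), size=min(label_mutations, len(interf)),
                           replace=False)
        for p in np.atleast_1d(picks):
            pid = interf[int(p)]
            current = atoms[pid].sybyl_type
            choices = [t for t in alphabet if t != current]
            atoms[pid].sybyl_type = str(rng.choice(choices))
            mutated.append(pid)

    planted_id = f"{host.complex_id}_planted"
    planted = MolecularComplex(planted_id, atoms, bonds,
                               source_path="<synthetic>")
    database = [d for i, d in enumerate(decoys) if i != host_idx] + [planted]
    truth = PlantedGroundTruth(
        planted_complex_id=planted_id, rotation=rotation,
        translation=translation, donor_to_planted=donor_to_planted,
        pocket_receptor_ids=tuple(pocket_receptor),
        mutated_planted_ids=tuple(mutated))

    if out_dir is not None:
        out_dir = Path(out_dir)
        for cx in database:
            sub = out_dir / cx.complex_id
            sub.mkdir(parents=True, exist_ok=True)
            write_complex(cx, sub / f"{cx.complex_id}_protein.mol2",
                          sub / f"{cx.complex_id}_ligand.mol2")
        with (out_dir / "ground_truth.tsv").open("w") as handle:
            handle.write("planted_complex_id\tdonor_atom_id\tplanted_atom_id\n")
            for src_id in sorted(donor_to_planted):
                handle.write(f"{planted_id}\t{src_id}\t"
                             f"{donor_to_planted[src_id]}\n")
    return database, truth


def transformed_copy(cx: MolecularComplex, seed: int = 0,
                     suffix: str = "_copy") -> tuple[
                         MolecularComplex, np.ndarray, np.ndarray]:
    """A rigidly transformed copy of a complex (for self-search fixtures)."""
    rng = np.random.default_rng([int(seed) % (2**31), 4049])
    rotation, translation = random_rigid_transform(rng)
    atoms = []
    for atom in cx.atoms:
        atoms.append(Atom(atom.id, atom.element, atom.sybyl_type,
                          rotation @ atom.coords + translation, atom.role,
                          atom.residue_tag, atom.name))
    copy = MolecularComplex(cx.complex_id + suffix, atoms, list(cx.bonds),
                            source_path="<synthetic>")
    return copy, rotation, translation


def make_random_interface_graph(n_nodes: int, seed: int = 0,
                                label_alphabet: tuple[str, ...] = DEFAULT_ALPHABET[:8],
                                radius: float = 3.2,
                                complex_id: str | None = None) -> InterfaceGraph:
    """A small random receptor-side interface graph for matcher tests.

    Nodes carry random labels and coordinates in a compact box; pairs within
    ``radius`` get nc edges, and a random spanning chain gets covalent
    single bonds, mirroring the mixed edge labeling of real interfaces.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 9001])
    side = max(2.0, 1.6 * n_nodes ** (1 / 3))
    coords = rng.uniform(0, side * 1.6, (n_nodes, 3))
    labels = rng.choice(label_alphabet, n_nodes)
    graph = nx.Graph()
    for v in range(n_nodes):
        graph.add_node(v, label=str(labels[v]), side="receptor",
                       interfacial=True, coords=coords[v])
    chain = rng.permutation(n_nodes)
    for a, b in zip(chain[:-1], chain[1:]):
        length = float(np.linalg.norm(coords[a] - coords[b]))
        graph.add_edge(int(a), int(b), label="1", length=length)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if graph.has_edge(i, j):
                continue
            length = float(np.linalg.norm(coords[i] - coords[j]))
            if length <= radius:
                graph.add_edge(i, j, label=NC, length=length)
    return InterfaceGraph(complex_id or f"rand{seed}", graph,
                          cutoff=radius, epsilon=0.0)
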