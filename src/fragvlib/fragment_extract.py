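"""Extraction of ligand fragments bound to matched pockets.

For every accepted pocket match the database ligand atoms in direct contact
with the matched receptor subgraph (their nc-edge neighbors, plus covalent
ligand neighbors for chemical completeness) are copied into the target
receptor's frame using the match's rigid transform. Copied atoms that
collide with the target receptor — closer than the safety distance to any
receptor heavy atom — are deleted. The surviving atoms, with their covalent
bonds and full source-complex provenance, form one fragment; all fragments
of a search form the virtual fragment library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .interface_graph import InterfaceGraph
from .pocket_match import PocketMatch
from .structure_io import MolecularComplex
from .sybyl import COVALENT_BOND_TYPES, NC

logger = logging.getLogger("fragvlib.fragment_extract")


@dataclass
class Fragment:
    """Ligand atoms copied into the target frame, with provenance.

    ``atoms`` holds (sybyl_type, coords-in-target-frame) pairs; ``bonds``
    index into that list. ``source_node_ids`` are the originating database
    graph node ids (same order as ``atoms``).
    """

    atoms: list[tuple[str, np.ndarray]]
    bonds: list[tuple[int, int, str]]
    source_complex_id: str
    match_rmsd: float
    match_index: int = 0
    source_node_ids: tuple[int, ...] = ()
    n_components: int = 1
    flagged_duplicate: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([c for _, c in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class FragmentLibrary:
    """Ordered fragment collection for one target, with the parameters used."""

    target_complex_id: str
    fragments: list[Fragment]
    params_used: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)


def contact_ligand_nodes(db_graph: InterfaceGraph,
                         match: PocketMatch) -> list[int]:
    """Ligand nodes in direct contact with the matched receptor subgraph.

    Direct contact means an nc edge to a matched receptor node; ligand-side
    covalent neighbors of contacted atoms are included as well (they are the
    padding atoms that complete the fragment chemistry). Waters never enter.
    """
    g = db_graph.graph
    matched = set(match.db_nodes)
    missing = matched - set(g.nodes)
    if missing:
        raise ValueError(f"match references nodes absent from the database "
                         f"graph: {sorted(missing)}")
    contact: set[int] = set()
    for m in matched:
        for nb in g[m]:
            if g.nodes[nb]["side"] == "ligand" and g[m][nb]["label"] == NC:
                contact.add(nb)
    padded = set(contact)
    for v in contact:
        for nb in g[v]:
            if (g.nodes[nb]["side"] == "ligand"
                    and g[v][nb]["label"] in COVALENT_BOND_TYPES):
                padded.add(nb)
    return sorted(padded)


def extract_fragment(db_complex: MolecularComplex, db_graph: InterfaceGraph,
                     match: PocketMatch, target: MolecularComplex,
                     safety_distance: float = 1.95,
                     match_index: int = 0) -> Fragment | None:
    """Copy the contacted ligand atoms into the target frame, drop collisions.

    Atoms strictly closer than ``safety_distance`` to any target receptor
    heavy atom are removed (their bonds with them); returns None when no
    ligand atom is in contact or none survives the collision filter. A
    fragment may end up with several connected components after pruning;
    the count is recorded.
    """
    selected = contact_ligand_nodes(db_graph, match)
    if not selected:
        logger.info("%s: match has no ligand contact; fragment skipped",
                    db_graph.complex_id)
        return None
    g = db_graph.graph
    coords_db = db_graph.coords_of(selected)
    moved = (match.rotation @ coords_db.T).T + match.translation

    receptor_coords = np.array(
        [a.coords for a in target.atoms if a.role == "receptor"], dtype=float)
    if len(receptor_coords) and safety_distance > 0:
        tree = cKDTree(receptor_coords)
        dmin, _ = tree.query(moved)
        keep = dmin >= safety_distance
    else:
        keep = np.ones(len(selected), dtype=bool)
    survivors = [v for v, k in zip(selected, keep) if k]
    if not survivors:
        logger.info("%s: all copied atoms collide with the target receptor",
                    db_graph.complex_id)
        return None

    sel_pos = {v: i for i, v in enumerate(selected)}
    local = {v: i for i, v in enumerate(survivors)}
    atoms = [(g.nodes[v]["label"], moved[sel_pos[v]]) for v in survivors]
    bonds = []
    for u, v in g.subgraph(survivors).edges:
        lbl = g[u][v]["label"]
        if lbl in COVALENT_BOND_TYPES:
            a, b = sorted((local[u], local[v]))
            bonds.append((a, b, lbl))
    bonds.sort()
    skeleton = nx.Graph()
    skeleton.add_nodes_from(range(len(survivors)))
    skeleton.add_edges_from((a, b) for a, b, _t in bonds)
    return Fragment(atoms=atoms, bonds=bonds,
                    source_complex_id=db_graph.complex_id,
                    match_rmsd=match.rmsd, match_index=match_index,
                    source_node_ids=tuple(survivors),
                    n_components=nx.number_connected_components(skeleton))


def assemble_library(fragments: list[Fragment], target_id: str,
                     params: dict | None = None) -> FragmentLibrary:
    """Order fragments by (source complex, match index) and flag duplicates.

    Duplicates (identical typed coordinates to 1e-3 Å, as produced by
    automorphic matches) are kept but flagged, so downstream consumers can
    filter without losing provenance.
    """
    ordered = sorted(fragments,
                     key=lambda f: (f.source_complex_id, f.match_index))
    seen: set[tuple] = set()
    for frag in ordered:
        key = tuple(sorted((t, round(float(x), 3), round(float(y), 3),
                            round(float(z), 3))
                           for t, (x, y, z) in frag.atoms))
        if key in seen:
            frag.flagged_duplicate = True
        else:
            seen.add(key)
    return FragmentLibrary(target_complex_id=target_id, fragments=ordered,
                           params_used=dict(params or {}))
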