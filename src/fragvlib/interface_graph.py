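"""Labeled interfacial graphs from (Almost-)Delaunay tessellation.

The binding interface of a complex is found by tessellating all heavy atoms
and keeping tessellation edges that cross between the receptor and ligand
(or water) sides within a distance cutoff. Endpoints of such edges are the
interfacial atoms; they become graph nodes together with their covalent
neighbors ("padding" nodes, which sharpen the chemical context). Edges carry
either a covalent bond label (1/2/3/am/ar) or the non-covalent label ``nc``
with the interatomic distance.

Almost-Delaunay (AD) relaxation: a contact also counts if it becomes a
Delaunay edge under a perturbation of the coordinates no larger than
``epsilon``, absorbing the imprecision of experimentally determined
coordinates. Here AD membership is estimated by resampling: seeded unit
displacement fields are applied at a fixed ladder of perturbation scales and
an edge is Almost-Delaunay at level eps if it appears in any replicate at a
scale <= eps. This preserves the two defining contract properties exactly:
AD(0) is the exact Delaunay edge set, and AD(eps) is monotone
non-decreasing in eps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structure_io import MolecularComplex
from .sybyl import NC

logger = logging.getLogger("fragvlib.interface_graph")

#: Absolute perturbation scales (Å) probed by the AD resampling estimate.
#: Epsilon-independent so that AD edge sets are monotone in epsilon.
AD_SCALE_LADDER: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)

#: Default number of jittered replicates per ladder scale.
AD_REPLICATES = 20


class DegenerateInputError(ValueError):
    """Too few points for a 3D tessellation; use the distance-graph mode."""


@dataclass(frozen=True)
class Simplex:
    """One tetrahedron of the tessellation.

    ``min_perturbation`` is the estimated smallest coordinate perturbation
    (Å) under which the simplex is Delaunay; 0 for exact Delaunay simplices.
    """

    vertex_ids: tuple[int, ...]
    min_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.vertex_ids)) != len(self.vertex_ids):
            raise ValueError("simplex vertices must be distinct")

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(p)) for p in combinations(self.vertex_ids, 2)]


def _deterministic_jitter(n: int, seed: int, scale: float) -> np.ndarray:
    """Reproducible symbolic jitter for degenerate (coplanar/cospherical)
    geometry, seeded from the point indices only."""
    rng = np.random.default_rng([int(seed) % (2**31), n, 977])
    return scale * rng.standard_normal((n, 3))


def delaunay_tessellation(points, jitter: bool = False,
                          seed: int = 0) -> list[Simplex]:
    """Exact 3D Delaunay tetrahedra of a point set (scipy/Qhull).

    Needs >= 5 points in general position; with ``jitter=True`` degenerate
    or minimal (4-point) inputs are perturbed by a deterministic 1e-6 Å
    displacement first. Raises :class:`DegenerateInputError` for inputs too
    small to tessellate, advising the all-pairs distance-graph mode.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(pts)
    minimum = 4 if jitter else 5
    if n < minimum:
        raise DegenerateInputError(
            f"{n} points cannot be tessellated in 3D; use the direct "
            "distance-graph mode (all pairs within the cutoff)")
    work = pts + _deterministic_jitter(n, seed, 1e-6) if jitter else pts
    try:
        tri = Delaunay(work)
    except QhullError:
        if jitter:
            raise
        logger.debug("degenerate geometry; retrying with deterministic jitter")
        tri = Delaunay(pts + _deterministic_jitter(n, seed, 1e-6))
    return [Simplex(tuple(sorted(int(v) for v in simplex)))
            for simplex in tri.simplices]


def _delaunay_edges(points: np.ndarray, jitter: bool,
                    seed: int) -> set[tuple[int, int]]:
    edges: set[tuple[int, int]] = set()
    for simplex in delaunay_tessellation(points, jitter=jitter, seed=seed):
        edges.update(simplex.edges())
    return edges


def almost_delaunay_edges(points, epsilon: float, n_replicates: int = AD_REPLICATES,
                          seed: int = 0) -> dict[tuple[int, int], float]:
    """Almost-Delaunay edge set at perturbation level ``epsilon``.

    Returns a mapping edge -> estimated min perturbation (0 for the exact
    Delaunay core). The result is a superset of the exact Delaunay edges and
    is monotone non-decreasing in epsilon (see module docstring for the
    resampling construction).
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = {e: 0.0 for e in _delaunay_edges(pts, jitter=False, seed=seed)}
    scales = [s for s in AD_SCALE_LADDER if s <= epsilon]
    for k in range(n_replicates):
        if not scales:
            break
        rng = np.random.default_rng([int(seed) % (2**31), k, 5113])
        # unit displacement field: uniform in the unit ball, per point
        unit = rng.standard_normal((n, 3))
        unit /= np.maximum(np.linalg.norm(unit, axis=1, keepdims=True), 1e-12)
        unit *= rng.uniform(0, 1, (n, 1)) ** (1 / 3)
        for scale in scales:
            for edge in _delaunay_edges(pts + scale * unit, jitter=False,
                                        seed=seed):
                prev = edges.get(edge)
                if prev is None or scale < prev:
                    edges[edge] = scale if prev is None else min(prev, scale)
    return edges


@dataclass
class InterfaceGraph:
    """Labeled undirected graph of interfacial atoms + covalent neighbors.

    Node attributes: ``label`` (SYBYL type), ``side`` (receptor/ligand/water),
    ``interfacial`` (False for covalent-padding nodes), ``coords``.
    Edge attributes: ``label`` (1/2/3/am/ar or nc), ``length`` (Å).
    """

    complex_id: str
    graph: nx.Graph
    cutoff: float
    epsilon: float
    include_waters: bool = False
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_on_side(self, side: str, interfacial_only: bool = False) -> list[int]:
        return sorted(
            v for v, d in self.graph.nodes(data=True)
            if d["side"] == side and (d["interfacial"] or not interfacial_only))

    @property
    def receptor_nodes(self) -> list[int]:
        return self.nodes_on_side("receptor")

    @property
    def interfacial_receptor_nodes(self) -> list[int]:
        return self.nodes_on_side("receptor", interfacial_only=True)

    def receptor_subgraph(self) -> nx.Graph:
        """Receptor-side view (interfacial + padding nodes, all edge types)."""
        return self.graph.subgraph(self.receptor_nodes)

    def coords_of(self, node_ids) -> np.ndarray:
        return np.array([self.graph.nodes[v]["coords"] for v in node_ids],
                        dtype=float).reshape(-1, 3)

    def write_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("u\tv\tlabel\tlength\n")
            for u, v, data in sorted(self.graph.edges(data=True)):
                handle.write(f"{u}\t{v}\t{data['label']}\t{data['length']:.4f}\n")

    def write_graphml(self, path: str | Path) -> None:
        dump = nx.Graph()
        for v, d in self.graph.nodes(data=True):
            x, y, z = d["coords"]
            dump.add_node(v, label=d["label"], side=d["side"],
                          interfacial=bool(d["interfacial"]),
                          x=float(x), y=float(y), z=float(z))
        for u, v, d in self.graph.edges(data=True):
            dump.add_edge(u, v, label=d["label"], length=float(d["length"]))
        nx.write_graphml(dump, str(path))


def build_interface_graph(complex_: MolecularComplex, cutoff: float = 5.8,
                          epsilon: float = 0.01, include_waters: bool = False,
                          seed: int = 0,
                          n_replicates: int = AD_REPLICATES) -> InterfaceGraph:
    """Build the labeled interfacial graph of a complex.

    Interfacial atoms are the endpoints of Almost-Delaunay edges that cross
    sides (receptor-ligand, and either side to water when included) with
    length <= cutoff. The graph contains those atoms plus their covalent
    neighbors; nc edges are the cross-side contacts and the intra-side AD
    edges between interfacial atoms (so each receptor side is a connected,
    distance-labeled subgraph); covalent bonds among included atoms keep
    their bond-type labels. An empty interface (no cross-side contact within
    the cutoff) yields an empty graph, not an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = [a for a in complex_.atoms
             if include_waters or a.role != "water"]
    by_id = {a.id: a for a in atoms}
    ids = [a.id for a in atoms]
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)

    bonded = {(min(b.a, b.b), max(b.a, b.b)): b.bond_type
              for b in complex_.bonds}

    # candidate contact edges: AD edges, or all pairs within the cutoff for
    # complexes too small to tessellate
    if len(atoms) < 5:
        logger.debug("%s: <5 atoms, falling back to all-pairs distance graph",
                     complex_.complex_id)
        ad = {}
        for i, j in combinations(range(len(atoms)), 2):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                ad[(i, j)] = 0.0
    else:
        ad = almost_delaunay_edges(coords, epsilon, n_replicates=n_replicates,
                                   seed=seed)

    def side(atom_id: int) -> str:
        return by_id[atom_id].role

    cross: list[tuple[int, int, float]] = []
    intra: list[tuple[int, int, float]] = []
    for (i, j), _pert in ad.items():
        u, v = ids[i], ids[j]
        length = float(np.linalg.norm(coords[i] - coords[j]))
        if length > cutoff:
            continue
        if (min(u, v), max(u, v)) in bonded:
            continue  # covalent pairs are never nc contacts
        su, sv = side(u), side(v)
        if su != sv:
            cross.append((u, v, length))
        elif su in ("receptor", "ligand"):
            intra.append((u, v, length))

    interfacial = set()
    for u, v, _ in cross:
        interfacial.add(u)
        interfacial.add(v)

    graph = nx.Graph()
    if not interfacial:
        logger.info("%s: empty interface (no cross-side contact within "
                    "%.2f Å)", complex_.complex_id, cutoff)
        return InterfaceGraph(complex_.complex_id, graph, cutoff, epsilon,
                              include_waters,
                              params={"seed": seed, "n_replicates": n_replicates})

    adjacency = complex_.neighbors()
    node_ids = set(interfacial)
    for v in interfacial:
        for nb, _btype in adjacency[v]:
            if nb in by_id:  # respects the water filter
                node_ids.add(nb)

    for v in sorted(node_ids):
        atom = by_id[v]
        graph.add_node(v, label=atom.sybyl_type, side=atom.role,
                       interfacial=v in interfacial,
                       coords=np.asarray(atom.coords, dtype=float))

    for u, v, length in cross:
        graph.add_edge(u, v, label=NC, length=length)
    for u, v, length in intra:
        if u in interfacial and v in interfacial:
            graph.add_edge(u, v, label=NC, length=length)
    for (a, b), btype in bonded.items():
        if a in node_ids and b in node_ids:
            length = float(np.linalg.norm(by_id[a].coords - by_id[b].coords))
            graph.add_edge(a, b, label=btype, length=length)

    return InterfaceGraph(complex_.complex_id, graph, cutoff, epsilon,
                          include_waters,
                          params={"seed": seed, "n_replicates": n_replicates})
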