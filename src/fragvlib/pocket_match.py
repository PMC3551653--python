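"""Receptor-side pocket matching by canonical-code subgraph growth.

Pocket similarity between two interfacial graphs is decided purely on the
receptor side: every connected induced receptor subgraph of the target
within a user-set size range is enumerated once per isomorphism class (a
canonical code deduplicates symmetric re-discoveries — the classic remedy
for redundant search in subgraph mining), embedded into the database
receptor side under exact node- and edge-label equality, and finally
verified geometrically: corresponding edge lengths must agree within a
tolerance and the matched nodes must superimpose (proper rotation only,
molecules are chiral) within an RMSD cutoff.

Subgraph isomorphism is NP-complete; the size range, the distance
prefilter, the RMSD cutoff and a per-pattern embedding cap are the
restrictions that keep the search tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .interface_graph import InterfaceGraph
from .sybyl import element_of

logger = logging.getLogger("fragvlib.pocket_match")


class ContractViolation(ValueError):
    """An operation precondition was violated (e.g. disconnected input)."""


@dataclass(frozen=True)
class MatchParams:
    """Knobs of the receptor-side match.

    ``distance_tolerance`` prefilters candidate embeddings by per-edge
    length agreement before the (more expensive) superposition;
    ``embedding_cap`` truncates pathological pattern/database pairs.
    ``element_labels`` coarsens node labels from full SYBYL types to bare
    elements.
    """

    min_size: int = 8
    max_size: int = 8
    rmsd_cutoff: float = 0.1
    distance_tolerance: float = 0.2
    embedding_cap: int = 10_000
    element_labels: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")
        if self.distance_tolerance < 0:
            raise ValueError("distance_tolerance must be >= 0")

    def node_label(self, raw: str) -> str:
        return element_of(raw) if self.element_labels else raw


@dataclass(frozen=True)
class SubgraphPattern:
    """One isomorphism class of connected receptor-side induced subgraphs.

    ``node_ids`` is the first-discovered occurrence in canonical vertex
    order; ``occurrences`` lists every target node tuple of the class, each
    ordered canonically so that position i corresponds across occurrences.
    ``code_nodes``/``code_edges`` give the class's labeled adjacency in
    canonical positions.
    """

    canonical_code: str
    node_ids: tuple[int, ...]
    occurrences: tuple[tuple[int, ...], ...]
    code_nodes: tuple[str, ...]
    code_edges: tuple[tuple[int, int, str], ...]

    @property
    def size(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class PocketMatch:
    """An accepted correspondence between target and database pockets.

    ``rotation``/``translation`` map database coordinates into the target
    frame (x_target ≈ R x_db + t); rotation is proper (det +1).
    """

    target_nodes: tuple[int, ...]
    db_nodes: tuple[int, ...]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    db_complex_id: str

    @property
    def size(self) -> int:
        return len(self.target_nodes)


# ---------------------------------------------------------------------------
# Canonical codes
# ---------------------------------------------------------------------------

def _canonical_order(graph: nx.Graph, node_ids, label_of) -> tuple[
        tuple[int, ...], tuple, tuple]:
    """Lexicographically minimal connected adjacency code, by branch and bound.

    Orderings are grown one vertex at a time (always adjacent to the chosen
    prefix, so the code doubles as a connected growth order); at each step
    only the orderings achieving the minimal next row survive. The code row
    of vertex i is (node label, sorted tuple of (j, edge label) over earlier
    neighbors j), which fully determines the labeled graph, so two vertex
    sets receive equal codes iff their induced subgraphs are isomorphic as
    labeled graphs.
    """
    nodes = list(node_ids)
    sub = graph.subgraph(nodes)
    if len(nodes) > 1 and not nx.is_connected(sub):
        raise ContractViolation("canonical_code requires a connected subgraph")
    n = len(nodes)
    start_label = min(label_of(v) for v in nodes)
    states = [(v,) for v in nodes if label_of(v) == start_label]
    rows = [(start_label, ())]
    for _depth in range(1, n):
        best_row = None
        extended: list[tuple[int, ...]] = []
        for order in states:
            placed = set(order)
            candidates = {u for v in order for u in sub[v] if u not in placed}
            for cand in candidates:
                row = (label_of(cand),
                       tuple(sorted((j, sub[order[j]][cand]["label"])
                                    for j in range(len(order))
                                    if sub.has_edge(order[j], cand))))
                if best_row is None or row < best_row:
                    best_row = row
                    extended = [order + (cand,)]
                elif row == best_row:
                    extended.append(order + (cand,))
        rows.append(best_row)  # type: ignore[arg-type]
        # dedupe identical orderings and bound the frontier
        states = list(dict.fromkeys(extended))
        if len(states) > 20_000:  # symmetric worst case; any minimal order works
            states = states[:20_000]
    order = states[0]
    code_nodes = tuple(r[0] for r in rows)
    code_edges = tuple(sorted(
        (j, i, sub[order[i]][order[j]]["label"])
        for i in range(n) for j in range(i)
        if sub.has_edge(order[i], order[j])))
    return order, (code_nodes, tuple(rows)), code_edges


def canonical_code(graph: InterfaceGraph | nx.Graph, node_ids,
                   params: MatchParams | None = None) -> str:
    """Canonical string for the labeled induced subgraph on ``node_ids``.

    Invariant under any permutation of the node ids; distinct for
    non-isomorphic labeled subgraphs. Edge lengths are excluded — geometry
    is checked separately at match time.
    """
    g = graph.graph if isinstance(graph, InterfaceGraph) else graph
    params = params or MatchParams(min_size=1)
    _, (_code_nodes, rows), _ = _canonical_order(
        g, node_ids, lambda v: params.node_label(g.nodes[v]["label"]))
    return _rows_to_str(rows)


def _rows_to_str(rows) -> str:
    return "|".join(
        f"{lbl};{','.join(f'{j}:{el}' for j, el in adj)}" for lbl, adj in rows)


# ---------------------------------------------------------------------------
# Pattern growth (ESU enumeration + canonical dedup)
# ---------------------------------------------------------------------------

def _connected_induced_subsets(graph: nx.Graph, min_size: int, max_size: int):
    """Enumerate every connected induced vertex subset with
    min_size <= |S| <= max_size exactly once (ESU enumeration)."""
    order = {v: i for i, v in enumerate(sorted(graph.nodes))}

    def extend(sub: frozenset, ext: set, root: int, forbidden: set):
        if len(sub) >= min_size:
            yield sub
        if len(sub) == max_size:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_forbidden = forbidden | {w} | set(graph[w])
            excl = {u for u in graph[w]
                    if order[u] > order[root] and u not in forbidden}
            yield from extend(sub | {w}, ext | excl, root, new_forbidden)

    for v in sorted(graph.nodes, key=lambda u: order[u]):
        ext0 = {u for u in graph[v] if order[u] > order[v]}
        yield from extend(frozenset([v]), ext0, v, {v} | set(graph[v]))


def grow_patterns(target: InterfaceGraph, params: MatchParams) -> list[SubgraphPattern]:
    """All connected receptor-side induced subgraphs of the target in the
    size range, deduplicated to one pattern per canonical code.

    Each pattern records every occurrence (isomorphic node sets appear as
    extra occurrences of the same pattern, not as new patterns).
    """
    receptor = target.receptor_subgraph()
    if receptor.number_of_nodes() < params.min_size:
        logger.warning("%s: receptor side has %d nodes < min_size %d",
                       target.complex_id, receptor.number_of_nodes(),
                       params.min_size)
        return []
    label_of = lambda v: params.node_label(receptor.nodes[v]["label"])  # noqa: E731
    by_code: dict[str, dict] = {}
    for subset in _connected_induced_subsets(receptor, params.min_size,
                                             params.max_size):
        order, (code_nodes, rows), code_edges = _canonical_order(
            receptor, subset, label_of)
        code = _rows_to_str(rows)
        entry = by_code.get(code)
        if entry is None:
            by_code[code] = {"order": order, "nodes": code_nodes,
                             "edges": code_edges, "occurrences": [order]}
        else:
            entry["occurrences"].append(order)
    patterns = []
    for code in sorted(by_code):
        entry = by_code[code]
        occurrences = tuple(sorted(entry["occurrences"]))
        patterns.append(SubgraphPattern(
            canonical_code=code, node_ids=occurrences[0],
            occurrences=occurrences, code_nodes=entry["nodes"],
            code_edges=entry["edges"]))
    return patterns


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a, coords_b) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal proper rigid superposition of b onto a.

    Returns (rotation, translation, rmsd) with rotation @ b + translation
    approximating a and det(rotation) = +1 (reflections are disallowed).
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ContractViolation(
            f"coordinate sets differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ContractViolation("cannot superpose empty coordinate sets")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    aa, bb = a - ca, b - cb
    h = bb.T @ aa
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ca - rotation @ cb
    residual = (rotation @ b.T).T + translation - a
    rmsd = float(np.sqrt((residual ** 2).sum() / len(a)))
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _embeddings(pattern: SubgraphPattern, db: nx.Graph, label_of,
                cap: int) -> list[tuple[int, ...]]:
    """Label-exact induced embeddings of a pattern into a database receptor
    side, by backtracking in canonical (connected) vertex order."""
    n = pattern.size
    # adjacency of the pattern in canonical positions
    pat_adj: list[dict[int, str]] = [dict() for _ in range(n)]
    for j, i, lbl in pattern.code_edges:
        pat_adj[i][j] = lbl
        pat_adj[j][i] = lbl
    by_label: dict[str, list[int]] = {}
    for v in db.nodes:
        by_label.setdefault(label_of(v), []).append(v)
    for vs in by_label.values():
        vs.sort()

    results: list[tuple[int, ...]] = []
    assigned: list[int] = []
    used: set[int] = set()
    truncated = False

    def backtrack(pos: int) -> None:
        nonlocal truncated
        if len(results) >= cap:
            truncated = True
            return
        if pos == n:
            results.append(tuple(assigned))
            return
        want_label = pattern.code_nodes[pos]
        earlier = pat_adj[pos]
        # anchor on a pattern neighbor already placed (pos>0 always has one)
        if pos == 0:
            candidates = by_label.get(want_label, [])
        else:
            anchor = min(earlier)
            candidates = [u for u in db[assigned[anchor]]
                          if label_of(u) == want_label]
            candidates.sort()
        for cand in candidates:
            if cand in used:
                continue
            ok = True
            for j in range(pos):
                lbl = earlier.get(j)
                if lbl is not None:
                    data = db.get_edge_data(cand, assigned[j])
                    if data is None or data["label"] != lbl:
                        ok = False
                        break
                elif db.has_edge(cand, assigned[j]):
                    ok = False  # induced: non-edges must stay non-edges
                    break
            if ok:
                assigned.append(cand)
                used.add(cand)
                backtrack(pos + 1)
                used.remove(cand)
                assigned.pop()

    backtrack(0)
    if truncated:
        logger.warning("embedding cap %d reached for a pattern of size %d; "
                       "match list truncated", cap, n)
    return results


def find_matches(target: InterfaceGraph, db_graph: InterfaceGraph,
                 params: MatchParams | None = None,
                 patterns: list[SubgraphPattern] | None = None) -> list[PocketMatch]:
    """All geometry-verified receptor-side pocket matches of target in db.

    Every (connected induced target subgraph, label-preserving bijection
    onto a database receptor subgraph) pair that passes the per-edge length
    prefilter and superimposes within the RMSD cutoff is returned; symmetric
    duplicates (identical target and database node sets related by an
    automorphism) are collapsed to the lowest-RMSD embedding. Output order
    is deterministic: size descending, then RMSD, then node ids.
    """
    params = params or MatchParams()
    if (abs(target.cutoff - db_graph.cutoff) > 1e-9
            or abs(target.epsilon - db_graph.epsilon) > 1e-9):
        logger.warning("target and database graphs were built with different "
                       "cutoff/epsilon settings; matches may be inconsistent")
    if patterns is None:
        patterns = grow_patterns(target, params)
    db_receptor = db_graph.receptor_subgraph()
    label_of = lambda v: params.node_label(db_receptor.nodes[v]["label"])  # noqa: E731

    best: dict[tuple[frozenset, frozenset], PocketMatch] = {}
    for pattern in patterns:
        embeddings = _embeddings(pattern, db_receptor, label_of,
                                 params.embedding_cap)
        if not embeddings:
            continue
        db_coord_cache = {emb: db_graph.coords_of(emb) for emb in embeddings}
        for occurrence in pattern.occurrences:
            t_coords = target.coords_of(occurrence)
            # per-edge lengths of this occurrence, in canonical positions
            t_graph = target.graph
            edge_lengths = [
                (i, j, t_graph[occurrence[i]][occurrence[j]]["length"])
                for j, i, _lbl in pattern.code_edges]
            for emb in embeddings:
                ok = True
                for i, j, t_len in edge_lengths:
                    d_len = db_graph.graph[emb[i]][emb[j]]["length"]
                    if abs(t_len - d_len) > params.distance_tolerance:
                        ok = False
                        break
                if not ok:
                    continue
                rotation, translation, rmsd = kabsch_superpose(
                    t_coords, db_coord_cache[emb])
                if rmsd > params.rmsd_cutoff:
                    continue
                key = (frozenset(occurrence), frozenset(emb))
                match = PocketMatch(occurrence, emb, rotation, translation,
                                    rmsd, db_graph.complex_id)
                prev = best.get(key)
                if (prev is None or match.rmsd < prev.rmsd
                        or (match.rmsd == prev.rmsd
                            and (match.target_nodes, match.db_nodes)
                            < (prev.target_nodes, prev.db_nodes))):
                    best[key] = match
    return sorted(best.values(),
                  key=lambda m: (-m.size, m.rmsd, m.target_nodes, m.db_nodes))


def write_match_tsv(matches, path) -> None:
    """Match report: db complex, size, rmsd, matched atom id lists."""
    from pathlib import Path

    with Path(path).open("w") as handle:
        handle.write("db_complex_id\tsize\trmsd\ttarget_atom_ids\tdb_atom_ids\n")
        for m in matches:
            handle.write(
                f"{m.db_complex_id}\t{m.size}\t{m.rmsd:.6f}\t"
                f"{','.join(map(str, m.target_nodes))}\t"
                f"{','.join(map(str, m.db_nodes))}\n")
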