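"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or direct
definition, sharing no code path with the implementation it checks (except
the Kabsch primitive, which is itself verified against a rotation-grid
optimum and scipy's align_vectors).
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import numpy as np

from fragvlib.pocket_match import MatchParams, kabsch_superpose
from fragvlib.sybyl import NC  # noqa: F401  (re-exported for tests)


# ---------------------------------------------------------------------------
# Delaunay via empty circumspheres
# ---------------------------------------------------------------------------

def delaunay_edges_bruteforce(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edge set by the definition: an edge belongs to the
    tessellation iff it lies in some tetrahedron whose circumsphere is empty
    of all other points (dual test over all 4-subsets)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for quad in combinations(range(n), 4):
        p = pts[list(quad)]
        a = 2 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue  # coplanar quadruple: no circumsphere
        radius = np.linalg.norm(p[0] - center)
        others = np.setdiff1d(np.arange(n), quad)
        dist = np.linalg.norm(pts[others] - center, axis=1)
        if np.all(dist > radius - 1e-9):
            edges.update(tuple(sorted(e)) for e in combinations(quad, 2))
    return edges


# ---------------------------------------------------------------------------
# Matching by exhaustive enumeration
# ---------------------------------------------------------------------------

def brute_force_matches(target, db, params: MatchParams) -> dict:
    """All geometry-verified matches by definition: every connected induced
    target receptor subgraph in the size range x every label-preserving
    bijection onto a db receptor subset that is an induced labeled-graph
    isomorphism, passes the per-edge length tolerance and superimposes
    within the RMSD cutoff. Collapsed like the implementation: one entry
    per (target node set, db node set), lowest rmsd.

    Returns {(frozenset(target), frozenset(db)): rmsd}.
    """
    tg, dg = target.graph.subgraph(target.receptor_nodes), \
        db.graph.subgraph(db.receptor_nodes)
    t_nodes = sorted(tg.nodes)
    d_nodes = sorted(dg.nodes)
    label = lambda g, v: params.node_label(g.nodes[v]["label"])  # noqa: E731

    # db subsets grouped by sorted label multiset, per size
    db_by_labels: dict[int, dict[tuple, list[tuple[int, ...]]]] = {}
    for k in range(params.min_size, params.max_size + 1):
        groups: dict[tuple, list[tuple[int, ...]]] = {}
        for subset in combinations(d_nodes, k):
            key = tuple(sorted(label(dg, v) for v in subset))
            groups.setdefault(key, []).append(subset)
        db_by_labels[k] = groups

    best: dict[tuple, float] = {}
    for k in range(params.min_size, params.max_size + 1):
        for t_subset in combinations(t_nodes, k):
            sub = tg.subgraph(t_subset)
            if not nx.is_connected(sub):
                continue
            t_key = tuple(sorted(label(tg, v) for v in t_subset))
            t_coords_all = {v: tg.nodes[v]["coords"] for v in t_subset}
            for d_subset in db_by_labels[k].get(t_key, []):
                for perm in permutations(d_subset):
                    mapping = dict(zip(t_subset, perm))
                    if any(label(tg, v) != label(dg, mapping[v])
                           for v in t_subset):
                        continue
                    ok = True
                    for u, v in combinations(t_subset, 2):
                        t_edge = tg.get_edge_data(u, v)
                        d_edge = dg.get_edge_data(mapping[u], mapping[v])
                        if (t_edge is None) != (d_edge is None):
                            ok = False
                            break
                        if t_edge is not None:
                            if t_edge["label"] != d_edge["label"]:
                                ok = False
                                break
                            if abs(t_edge["length"] - d_edge["length"]) > \
                                    params.distance_tolerance:
                                ok = False
                                break
                    if not ok:
                        continue
                    a = np.array([t_coords_all[v] for v in t_subset])
                    b = np.array([dg.nodes[mapping[v]]["coords"]
                                  for v in t_subset])
                    _r, _t, rmsd = kabsch_superpose(a, b)
                    if rmsd > params.rmsd_cutoff:
                        continue
                    key = (frozenset(t_subset), frozenset(perm))
                    if key not in best or rmsd < best[key]:
                        best[key] = rmsd
    return best


# ---------------------------------------------------------------------------
# Superposition optimum over a rotation grid
# ---------------------------------------------------------------------------

def rmsd_rotation_grid(a: np.ndarray, b: np.ndarray, n_grid: int = 24) -> float:
    """Best superposition RMSD by scanning proper rotations on an Euler grid
    and polishing the best cell with Nelder-Mead (translation eliminated by
    centering). Independent of the closed-form solution."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    aa = a - a.mean(axis=0)
    bb = b - b.mean(axis=0)

    def cost_rot(rot: Rotation) -> float:
        return float(np.sqrt((((rot.apply(bb)) - aa) ** 2).sum() / len(a)))

    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    beta = np.linspace(0, np.pi, n_grid // 2 + 1)
    best_val, best_euler = np.inf, None
    for e1 in grid:
        for e2 in beta:
            for e3 in grid:
                val = cost_rot(Rotation.from_euler("zyz", [e1, e2, e3]))
                if val < best_val:
                    best_val, best_euler = val, [e1, e2, e3]
    res = minimize(lambda e: cost_rot(Rotation.from_euler("zyz", e)),
                   best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return float(min(best_val, res.fun))
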