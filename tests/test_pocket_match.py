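"""Canonical codes, pattern growth, Kabsch superposition and matching."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragvlib as fv
from fragvlib.fixtures import make_random_interface_graph, transformed_copy
from fragvlib.interface_graph import InterfaceGraph
from fragvlib.pocket_match import ContractViolation, MatchParams
from oracles import brute_force_matches, rmsd_rotation_grid


def _labeled_graph(edges, labels):
    g = nx.Graph()
    for v, lbl in labels.items():
        g.add_node(v, label=lbl, side="receptor", interfacial=True,
                   coords=np.zeros(3))
    for u, v, lbl in edges:
        g.add_edge(u, v, label=lbl, length=1.0)
    return g


class TestCanonicalCode:
    def test_permutation_invariance(self):
        labels = {0: "C.3", 1: "N.am", 2: "C.2", 3: "O.3", 4: "C.ar"}
        edges = [(0, 1, "1"), (1, 2, "am"), (2, 3, "nc"), (3, 4, "1"),
                 (0, 4, "nc")]
        g1 = _labeled_graph(edges, labels)
        perm = {0: 3, 1: 0, 2: 4, 3: 1, 4: 2}
        g2 = _labeled_graph([(perm[u], perm[v], l) for u, v, l in edges],
                            {perm[v]: l for v, l in labels.items()})
        assert fv.canonical_code(g1, list(g1)) == \
            fv.canonical_code(g2, list(g2))

    def test_different_adjacency_different_codes(self):
        path1 = _labeled_graph([(0, 1, "1"), (1, 2, "1")],
                               {0: "C.3", 1: "N.am", 2: "C.2"})
        path2 = _labeled_graph([(0, 1, "1"), (1, 2, "1")],
                               {0: "C.3", 1: "C.2", 2: "N.am"})
        assert fv.canonical_code(path1, [0, 1, 2]) != \
            fv.canonical_code(path2, [0, 1, 2])

    def test_disconnected_input_rejected(self):
        g = _labeled_graph([(0, 1, "1")], {0: "C.3", 1: "C.3", 2: "C.3"})
        with pytest.raises(ContractViolation):
            fv.canonical_code(g, [0, 1, 2])

    def test_code_classes_match_isomorphism_classes(self):
        # all connected 3-node subgraphs of a random labeled 10-node graph:
        # number of distinct codes == number of isomorphism classes found
        # by pairwise VF2 testing
        ig = make_random_interface_graph(10, seed=5)
        g = ig.graph
        subs = [s for s in combinations(g.nodes, 3)
                if nx.is_connected(g.subgraph(s))]
        codes = {s: fv.canonical_code(g, s) for s in subs}
        nm = nx.algorithms.isomorphism.categorical_node_match("label", None)
        em = nx.algorithms.isomorphism.categorical_edge_match("label", None)
        classes: list[list] = []
        for s in subs:
            for cls in classes:
                if nx.is_isomorphic(g.subgraph(s), g.subgraph(cls[0]),
                                    node_match=nm, edge_match=em):
                    cls.append(s)
                    break
            else:
                classes.append([s])
        assert len(set(codes.values())) == len(classes)
        for cls in classes:
            assert len({codes[s] for s in cls}) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), perm_seed=st.integers(0, 10_000))
    def test_code_invariant_under_random_relabeling(self, seed, perm_seed):
        ig = make_random_interface_graph(7, seed=seed)
        g = ig.graph
        rng = np.random.default_rng(perm_seed)
        perm = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, perm)
        comp = max(nx.connected_components(g), key=len)
        assert fv.canonical_code(g, comp) == \
            fv.canonical_code(h, [perm[v] for v in comp])


class TestGrowPatterns:
    def _path_graph(self, labels):
        g = nx.Graph()
        coords = np.arange(len(labels) * 3, dtype=float).reshape(-1, 3)
        for i, lbl in enumerate(labels):
            g.add_node(i, label=lbl, side="receptor", interfacial=True,
                       coords=coords[i])
        for i in range(len(labels) - 1):
            g.add_edge(i, i + 1, label="1", length=1.5)
        return InterfaceGraph("path", g, cutoff=5.8, epsilon=0.0)

    def test_path_counts_match_exhaustive_enumeration(self):
        ig = self._path_graph(["C.3", "N.am", "C.2", "O.3"])
        patterns = fv.grow_patterns(ig, MatchParams(min_size=2, max_size=4,
                                                    rmsd_cutoff=1.0))
        occurrences_by_size = {}
        for p in patterns:
            occurrences_by_size.setdefault(p.size, 0)
            occurrences_by_size[p.size] += len(p.occurrences)
        # a 4-path has 3 connected pairs, 2 connected triples, 1 quadruple
        assert occurrences_by_size == {2: 3, 3: 2, 4: 1}

    def test_singletons_one_pattern_per_label(self):
        ig = self._path_graph(["C.3", "N.am", "C.3", "O.3"])
        patterns = fv.grow_patterns(ig, MatchParams(min_size=1, max_size=1,
                                                    rmsd_cutoff=1.0))
        assert len(patterns) == 3  # C.3, N.am, O.3
        sizes = {p.canonical_code: len(p.occurrences) for p in patterns}
        assert sorted(sizes.values()) == [1, 1, 2]

    def test_no_pattern_spans_disconnected_components(self):
        g = nx.Graph()
        for i, lbl in enumerate(["C.3", "C.3", "N.3", "N.3"]):
            g.add_node(i, label=lbl, side="receptor", interfacial=True,
                       coords=np.array([float(i), 0.0, 0.0]))
        g.add_edge(0, 1, label="1", length=1.0)
        g.add_edge(2, 3, label="1", length=1.0)
        ig = InterfaceGraph("two", g, cutoff=5.8, epsilon=0.0)
        patterns = fv.grow_patterns(ig, MatchParams(min_size=2, max_size=4,
                                                    rmsd_cutoff=1.0))
        for p in patterns:
            for occ in p.occurrences:
                assert set(occ) <= {0, 1} or set(occ) <= {2, 3}

    def test_min_size_above_receptor_count_warns_empty(self, small_graph):
        n = len(small_graph.receptor_nodes)
        patterns = fv.grow_patterns(small_graph,
                                    MatchParams(min_size=n + 5,
                                                max_size=n + 5))
        assert patterns == []


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(0, 3, (6, 3))
        rotation, translation, rmsd = fv.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rotation, np.eye(3), atol=1e-9)
        assert np.allclose(translation, 0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 5, (8, 3))
        from fragvlib.fixtures import random_rigid_transform
        rot_true, t_true = random_rigid_transform(rng)
        b = (rot_true.T @ (a - t_true).T).T  # b such that rot_true@b+t_true=a
        rotation, translation, rmsd = fv.kabsch_superpose(a, b)
        assert rmsd <= 1e-9
        assert np.allclose(rotation, rot_true, atol=1e-8)
        assert np.allclose(translation, t_true, atol=1e-7)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_on_three_points(self):
        # axis points, with one displaced: non-trivial optimum
        a = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        b = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0.4, 1.2]])
        _r, _t, rmsd = fv.kabsch_superpose(a, b)
        grid_opt = rmsd_rotation_grid(a, b)
        assert rmsd == pytest.approx(grid_opt, abs=1e-3)
        assert rmsd <= grid_opt + 1e-9  # closed form can't be worse

    def test_matches_scipy_align_vectors(self, rng):
        from scipy.spatial.transform import Rotation
        a = rng.normal(0, 2, (7, 3))
        b = rng.normal(0, 2, (7, 3))
        _r, _t, rmsd = fv.kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractViolation):
            fv.kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


def _loose_params(**kw):
    defaults = dict(min_size=2, max_size=3, rmsd_cutoff=1.0,
                    distance_tolerance=1.5)
    defaults.update(kw)
    return MatchParams(**defaults)


def _match_keys(matches):
    return {(frozenset(m.target_nodes), frozenset(m.db_nodes)): m.rmsd
            for m in matches}


class TestFindMatches:
    def test_self_search_recovers_full_size(self, small_complex):
        ig = fv.build_interface_graph(small_complex)
        copy_cx, _r, _t = transformed_copy(small_complex, seed=3)
        ig_copy = fv.build_interface_graph(copy_cx)
        size = min(8, len(ig.interfacial_receptor_nodes))
        matches = fv.find_matches(ig, ig_copy,
                                  MatchParams(min_size=size, max_size=size))
        assert matches
        assert matches[0].size == size
        assert min(m.rmsd for m in matches) <= 1e-6

    def test_mutated_label_excludes_node(self):
        target = make_random_interface_graph(9, seed=21)
        db = target.graph.copy()
        victim = sorted(db.nodes)[4]
        db.nodes[victim]["label"] = "I"  # label absent from the alphabet
        db_ig = InterfaceGraph("mut", db, target.cutoff, target.epsilon)
        matches = fv.find_matches(target, db_ig, _loose_params())
        assert all(victim not in m.db_nodes for m in matches)

    @pytest.mark.parametrize("pair_seed", [0, 1, 2])
    def test_agrees_with_brute_force(self, pair_seed):
        target = make_random_interface_graph(9, seed=2 * pair_seed)
        db = make_random_interface_graph(9, seed=2 * pair_seed + 1)
        params = _loose_params()
        ours = _match_keys(fv.find_matches(target, db, params))
        oracle = brute_force_matches(target, db, params)
        assert set(ours) == set(oracle)
        for key, rmsd in ours.items():
            assert rmsd == pytest.approx(oracle[key], abs=1e-9)

    def test_rmsd_invariant_under_db_rigid_motion(self, small_complex):
        ig = fv.build_interface_graph(small_complex)
        params = MatchParams(min_size=4, max_size=4)
        copy1, _, _ = transformed_copy(small_complex, seed=10)
        copy2, _, _ = transformed_copy(copy1, seed=11, suffix="")
        m1 = _match_keys(fv.find_matches(
            ig, fv.build_interface_graph(copy1), params))
        m2 = _match_keys(fv.find_matches(
            ig, fv.build_interface_graph(copy2), params))
        assert set(m1) == set(m2)
        for key in m1:
            assert abs(m1[key] - m2[key]) <= 1e-9

    def test_monotone_in_thresholds(self):
        target = make_random_interface_graph(10, seed=31)
        db = make_random_interface_graph(10, seed=32)
        tight = _loose_params(rmsd_cutoff=0.5, distance_tolerance=0.8,
                              min_size=3, max_size=3)
        loose = _loose_params(rmsd_cutoff=1.5, distance_tolerance=2.0,
                              min_size=2, max_size=4)
        assert set(_match_keys(fv.find_matches(target, db, tight))) <= \
            set(_match_keys(fv.find_matches(target, db, loose)))

    def test_deterministic_output(self):
        target = make_random_interface_graph(9, seed=41)
        db = make_random_interface_graph(9, seed=42)
        runs = [fv.find_matches(target, db, _loose_params())
                for _ in range(2)]
        assert [(m.target_nodes, m.db_nodes, m.rmsd) for m in runs[0]] == \
            [(m.target_nodes, m.db_nodes, m.rmsd) for m in runs[1]]

    def test_element_level_labels_widen_matches(self):
        target = make_random_interface_graph(8, seed=51)
        db = make_random_interface_graph(8, seed=52)
        strict = _match_keys(fv.find_matches(target, db, _loose_params()))
        coarse = _match_keys(fv.find_matches(
            target, db, _loose_params(element_labels=True)))
        assert set(strict) <= set(coarse)
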