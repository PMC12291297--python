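"""k-path tree, canonical form, criteria, reconstruction, closedness."""

import numpy as np
import pytest

from ms2patterns.graphs import GraphDB
from ms2patterns.mining import (MiningParams, MiningStats, Pattern, Subtree,
                                build_k_path_tree, is_closed,
                                lmdf_encode, mine_closed_patterns,
                                reconstruct_pattern)
from ms2patterns.synth import (are_isomorphic, brute_force_mine,
                               miner_output_keys, random_graphdb)


def _label_by_center(db: GraphDB, center: float) -> int:
    return next(l.id for l in db.labels if abs(l.center - center) < 0.01)


# ---------------------------------------------------------------------------
# k-path tree


class TestKPathTree:
    def test_two_loss_orders_share_closing_label(self, diamond_db):
        """The CO2->H2O path node closes onto the same combined-loss label
        in both graphs and is rooted at the precursor vertex of each."""
        h2o = _label_by_center(diamond_db, 18.010565)
        co2 = _label_by_center(diamond_db, 43.989829)
        ch2o3 = _label_by_center(diamond_db, 62.000394)
        tree = build_k_path_tree(diamond_db, MiningParams(min_support=2))
        node = tree.root.children[co2].children[h2o]
        assert node.h == ch2o3
        assert node.occ == {(0, 3), (1, 3)}  # precursor is vertex 3
        # the mirrored order exists too, with the same closing label
        assert tree.root.children[h2o].children[co2].h == ch2o3

    def test_nothing_frequent_gives_bare_root(self, diamond_db):
        solo = GraphDB(diamond_db.graphs[:1], diamond_db.labels,
                       diamond_db.params)
        tree = build_k_path_tree(solo, MiningParams(min_support=2))
        assert tree.root.children == {}
        assert tree.n_paths() == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_node_count_matches_exhaustive_path_enumeration(self, seed):
        """Tree nodes correspond one-to-one to the distinct frequent
        directed label paths, counted by exhaustive DFS."""
        rng = np.random.default_rng(1000 + seed)
        db = random_graphdb(rng)
        params = MiningParams(min_support=2)
        tree = build_k_path_tree(db, params)

        paths: dict[tuple, set[int]] = {}
        for gi, g in enumerate(db.graphs):
            out = g.out_map()

            def walk(v, labels):
                if labels:
                    paths.setdefault(tuple(labels), set()).add(gi)
                if len(labels) >= tree.k:
                    return
                for lab, t in out[v].items():
                    walk(t, labels + [lab])

            for v in range(g.n_vertices):
                walk(v, [])
        frequent = sum(1 for s in paths.values()
                       if len(s) >= params.min_support)
        assert tree.n_paths() == frequent


# ---------------------------------------------------------------------------
# canonical form


def _random_afg(rng, n_max=6, n_labels=8):
    n = int(rng.integers(2, n_max + 1))
    edges = []
    used = {v: set() for v in range(n)}
    pairs = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        lab = int(rng.integers(0, n_labels))
        while lab in used[u]:
            lab = int(rng.integers(0, n_labels))
        edges.append((u, v, lab))
        used[u].add(lab)
        pairs.add((u, v))
    for _ in range(int(rng.integers(0, n))):
        u = int(rng.integers(0, n - 1))
        v = int(rng.integers(u + 1, n))
        if (u, v) in pairs or len(used[u]) >= n_labels:
            continue
        lab = int(rng.integers(0, n_labels))
        while lab in used[u]:
            lab = int(rng.integers(0, n_labels))
        edges.append((u, v, lab))
        used[u].add(lab)
        pairs.add((u, v))
    return 0, list(range(n)), edges


def _relabel(afg, rng):
    root, vertices, edges = afg
    perm = [root] + list(rng.permutation([v for v in vertices if v != root]))
    f = {old: new for new, old in enumerate(perm)}
    return f[root], sorted(f.values()), [(f[u], f[v], lab)
                                         for u, v, lab in edges]


def _pattern(afg) -> Pattern:
    root, vertices, edges = afg
    return Pattern(root, vertices, edges, frozenset(), [])


class TestLmdfEncode:
    def test_depth1_star_visits_labels_in_order(self):
        star = _pattern((0, [0, 1, 2, 3], [(0, 1, 3), (0, 2, 7), (0, 3, 9)]))
        tokens, edges = lmdf_encode(star, k=14)
        assert tokens == (("d", 3), ("u", -1), ("d", 7), ("u", -1),
                          ("d", 9), ("u", -1))
        assert len(edges) == 3

    def test_vertex_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = _random_afg(rng)
            assert lmdf_encode(_pattern(g)) == lmdf_encode(_pattern(_relabel(g, rng)))

    def test_codes_equal_iff_isomorphic(self):
        """Cross-check against an exhaustive vertex-map isomorphism search
        on 1000 seeded AFG pairs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            g1 = _random_afg(rng)
            g2 = (_relabel(g1, rng) if rng.random() < 0.5
                  else _random_afg(rng))
            same_code = lmdf_encode(_pattern(g1)) == lmdf_encode(_pattern(g2))
            assert same_code == are_isomorphic(g1, g2)

    def test_rejects_non_afg(self):
        with pytest.raises(ValueError):
            lmdf_encode(_pattern((0, [0, 1], [(0, 1, 1), (1, 0, 2)])))
        with pytest.raises(ValueError):  # vertex 2 unreachable
            lmdf_encode(Pattern(0, [0, 1, 2], [(0, 1, 1)], frozenset(), []))


# ---------------------------------------------------------------------------
# criteria and reconstruction


class TestMining:
    def test_diamond_mined_as_single_closed_pattern(self, diamond_db):
        """Sub-patterns of the diamond share its support and are pruned as
        non-closed; the star subtree duplicating the combined-loss vertex
        is rejected by the spanning-tree criterion."""
        stats = MiningStats()
        pats = mine_closed_patterns(diamond_db, MiningParams(min_support=2),
                                    stats=stats)
        assert len(pats) == 1
        (p,) = pats
        assert p.support == frozenset({0, 1})
        assert len(p.vertices) == 4 and len(p.edges) == 5
        assert stats.failed_spanning > 0  # e.g. H2O->CO2 + CO2->H2O subtree
        assert stats.not_closed > 0

    def test_mined_patterns_have_depth1_root_star_and_unique_codes(self):
        rng = np.random.default_rng(3)
        codes = []
        for _ in range(10):
            db = random_graphdb(rng)
            pats = mine_closed_patterns(db, MiningParams(min_support=2))
            for p in pats:
                roots_out = {v for u, v, _ in p.edges if u == p.root}
                assert roots_out == set(p.vertices) - {p.root}
                h = list(p.h_labels().values())
                assert len(set(h)) == len(h)
            codes = [p.canonical_code for p in pats]
            assert len(set(codes)) == len(codes)

    def test_matches_bruteforce_on_random_databases(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            db = random_graphdb(rng)
            pats = mine_closed_patterns(db, MiningParams(min_support=2))
            assert miner_output_keys(pats) == brute_force_mine(db, 2)

    def test_support_confirmed_by_independent_embedding_search(self):
        from ms2patterns.synth import _embeds, _enumerate_afgs, _shape_from
        rng = np.random.default_rng(23)
        for _ in range(5):
            db = random_graphdb(rng)
            pats = mine_closed_patterns(db, MiningParams(min_support=2))
            for p in pats:
                shape = _shape_from(p.root, p.vertices, p.edges)
                found = set()
                for gi, g in enumerate(db.graphs):
                    for key, root, subset, edges in _enumerate_afgs(g, gi):
                        if key == shape.key:
                            found.add(gi)
                assert frozenset(found) == p.support

    def test_sub_afg_support_anti_monotone(self):
        from ms2patterns.synth import _embeds, _shape_from
        rng = np.random.default_rng(29)
        db = random_graphdb(rng)
        pats = mine_closed_patterns(db, MiningParams(min_support=2))
        for p in pats:
            sinks = [v for v in p.vertices if v != p.root
                     and not any(u == v for u, _, _ in p.edges)]
            for drop in sinks:
                verts = [v for v in p.vertices if v != drop]
                edges = [e for e in p.edges if drop not in e[:2]]
                if len(edges) == 0:
                    continue
                sub = _shape_from(p.root, verts, edges)
                supp = sum(
                    1 for g in db.graphs
                    if any(_embeds(sub, _shape_from(r, list(s), e))
                           for _, r, s, e in _iter_afgs_once(g)))
                assert supp >= len(p.support)

    def test_minsupp_above_database_size_yields_nothing(self, diamond_db):
        assert mine_closed_patterns(diamond_db,
                                    MiningParams(min_support=3)) == []

    def test_max_pattern_size_caps_edges(self, diamond_db):
        pats = mine_closed_patterns(
            diamond_db, MiningParams(min_support=2, max_pattern_size=3))
        assert all(p.n_edges <= 3 for p in pats)


def _iter_afgs_once(g):
    from ms2patterns.synth import _enumerate_afgs
    yield from _enumerate_afgs(g, 0)


class TestReconstruction:
    def test_star_subtree_over_triangle_gains_transversal_edge(self, triangle_db):
        h2o = _label_by_center(triangle_db, 18.010565)
        h4o2 = _label_by_center(triangle_db, 36.02113)
        tree = build_k_path_tree(triangle_db, MiningParams(min_support=2))
        n1, n2 = tree.root.children[h2o], tree.root.children[h4o2]
        subtree = Subtree([n1, n2], [-1, -1], n1.occ & n2.occ)
        p = reconstruct_pattern(subtree, triangle_db)
        assert len(p.edges) == 3  # the H2O edge between the two losses added
        labs = sorted(lab for _, _, lab in p.edges)
        assert labs == sorted([h2o, h2o, h4o2])

    def test_subtree_equal_to_full_subgraph_unchanged(self, diamond_db):
        h2o = _label_by_center(diamond_db, 18.010565)
        tree = build_k_path_tree(diamond_db, MiningParams(min_support=2))
        n = tree.root.children[h2o]
        p = reconstruct_pattern(Subtree([n], [-1], n.occ), diamond_db)
        assert len(p.edges) == 1

    def test_reconstructed_edges_present_in_all_occurrences(self):
        from ms2patterns.mining import verify_occurrences
        rng = np.random.default_rng(31)
        for _ in range(5):
            db = random_graphdb(rng)
            for p in mine_closed_patterns(db, MiningParams(min_support=2)):
                assert verify_occurrences(p, db) == []


class TestIsClosed:
    def _single_edge_pattern(self, db, lab, occs):
        edges = [(0, 1, lab)]
        occurrences = [(g, v, {0: v, 1: db.graphs[g].out_map()[v][lab]})
                       for g, v in occs]
        return Pattern(0, [0, 1], edges,
                       frozenset(g for g, _ in occs), occurrences)

    def test_common_extra_root_edge_means_not_closed(self, diamond_db):
        h2o = _label_by_center(diamond_db, 18.010565)
        p = self._single_edge_pattern(diamond_db, h2o, [(0, 3), (1, 3)])
        assert not is_closed(p, diamond_db)  # every root also emits CO2

    def test_no_common_extension_means_closed(self, diamond_db):
        pats = mine_closed_patterns(diamond_db, MiningParams(min_support=2))
        assert all(is_closed(p, diamond_db) for p in pats)

    def test_empty_occurrences_rejected(self, diamond_db):
        p = Pattern(0, [0, 1], [(0, 1, 0)], frozenset(), [])
        with pytest.raises(ValueError):
            is_closed(p, diamond_db)

    def test_agrees_with_single_extension_oracle(self):
        """Definition-12 check: a frequent pattern is closed iff no 1-edge
        root extension keeps its support, verified by the exhaustive
        enumerate-and-embed oracle over 500+ frequent candidates."""
        from ms2patterns.synth import _embeds, _enumerate_afgs, _shape_from
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 500:
            db = random_graphdb(rng)
            support: dict[tuple, set] = {}
            first: dict[tuple, tuple] = {}
            occs: dict[tuple, list] = {}
            for gi, g in enumerate(db.graphs):
                for key, root, subset, edges in _enumerate_afgs(g, gi):
                    support.setdefault(key, set()).add(gi)
                    occs.setdefault(key, []).append((gi, root, subset, edges))
                    first.setdefault(key, (root, subset, edges))
            frequent = {k: frozenset(v) for k, v in support.items()
                        if len(v) >= 2}
            for key, supp in frequent.items():
                root, subset, edges = first[key]
                index = {v: i for i, v in enumerate(subset)}
                p_edges = [(index[u], index[v], lab) for u, v, lab in edges]
                # is_closed only needs each occurrence's mapped root vertex
                occurrences = [(gi, r, {}) for gi, r, _, _ in occs[key]]
                p = Pattern(index[root], list(range(len(subset))), p_edges,
                            supp, occurrences)
                cand = _shape_from(p.root, p.vertices, p.edges)
                dominated = any(
                    ko != key and so == supp
                    and (len(_key_names(ko)) > len(_key_names(key))
                         or len(ko) > len(key))
                    and _embeds(cand, _shape_from_key(ko))
                    for ko, so in frequent.items())
                assert is_closed(p, db) == (not dominated)
                checked += 1
        assert checked >= 500


def _key_names(key):
    names = set()
    for u, v, _ in key:
        names.add(u)
        names.add(v)
    return names


def _shape_from_key(key):
    from ms2patterns.synth import _Candidate
    return _Candidate(key, tuple(sorted(_key_names(key) | {()})), key)
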