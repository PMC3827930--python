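"""Family placement: distance matrices, NJ recovery, clade-based assignment."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from lipmine import (
    DistanceMatrix,
    InputError,
    ProteinRecord,
    assign_family,
    build_distance_matrix,
    global_align,
    neighbor_joining,
    place,
    select_top_candidates,
)
from conftest import family_panel, mutate


def random_additive_tree(n_leaves, rng):
    """Random binary unrooted tree; returns (edges dict, leaf names)."""
    import networkx as nx

    g = nx.Graph()
    g.add_node("i0")
    leaves = []
    for k in range(3):
        name = f"t{k}"
        g.add_edge("i0", name, weight=float(rng.uniform(0.01, 0.06)))
        leaves.append(name)
    next_internal = 1
    for k in range(3, n_leaves):
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.25, 0.75))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        name = f"t{k}"
        g.add_edge(mid, name, weight=float(rng.uniform(0.01, 0.06)))
        leaves.append(name)
    return g, sorted(leaves)


def tree_splits(g, leaves):
    """Non-trivial bipartitions of a networkx tree, canonicalised."""
    import networkx as nx

    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in leaves}
        if 1 < len(side) < len(leaves) - 1:
            if leaves[0] not in side:
                side = set(leaves) - side
            splits.add(frozenset(side))
    return splits


def newick_splits(newick, leaves):
    tree = TreeNode.read(io.StringIO(newick))
    splits = set()
    for node in tree.traverse(include_self=False):
        if not node.children:
            continue
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(leaves) - 1:
            if leaves[0] not in side:
                side = set(leaves) - side
            splits.add(frozenset(side))
    return splits


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        recs = [ProteinRecord(id=f"s{i}", seq="MKVLLAGHW") for i in range(3)]
        m = build_distance_matrix(recs)
        assert np.allclose(m.values, 0.0)

    def test_symmetry_of_pair_distance(self):
        a, b = "MKVLLAGHWDE", "MKILAGWDE"
        da = 1 - global_align(a, b).identity_percent / 100
        db = 1 - global_align(b, a).identity_percent / 100
        assert da == pytest.approx(db)

    def test_entries_match_per_pair_recomputation(self):
        rng = np.random.default_rng(7)
        recs = [ProteinRecord(id=f"s{i}",
                              seq="".join(rng.choice(list("ACDEFGHIK"), 40)))
                for i in range(5)]
        m = build_distance_matrix(recs)
        for i in range(5):
            for j in range(i + 1, 5):
                expect = 1 - global_align(recs[i].seq, recs[j].seq).identity_percent / 100
                assert m.values[i, j] == pytest.approx(expect)

    def test_duplicate_labels_rejected(self):
        recs = [ProteinRecord(id="x", seq="MKV"), ProteinRecord(id="x", seq="MKA"),
                ProteinRecord(id="y", seq="MKC")]
        with pytest.raises(InputError):
            build_distance_matrix(recs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InputError):
            DistanceMatrix(labels=("a", "b"),
                           values=np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.4],
                      [0.3, 0.0, 0.5],
                      [0.4, 0.5, 0.0]])
        nwk = neighbor_joining(DistanceMatrix(labels=("a", "b", "c"), values=d))
        tree = TreeNode.read(io.StringIO(nwk))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["c"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    def test_recovers_additive_topologies(self):
        import networkx as nx

        rng = np.random.default_rng(29)
        for trial in range(20):
            n = int(rng.integers(5, 9))
            g, leaves = random_additive_tree(n, rng)
            d = np.zeros((n, n))
            paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for i, a in enumerate(leaves):
                for j, b in enumerate(leaves):
                    d[i, j] = paths[a][b]
            nwk = neighbor_joining(DistanceMatrix(labels=tuple(leaves), values=d))
            assert newick_splits(nwk, leaves) == tree_splits(g, leaves), trial

    def test_tie_break_deterministic(self):
        # two equal minimal Q entries -> lexicographically first pair joined
        d = np.array([
            [0.0, 0.2, 0.4, 0.4],
            [0.2, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.2],
            [0.4, 0.4, 0.2, 0.0],
        ])
        m = DistanceMatrix(labels=("a", "b", "c", "d"), values=d)
        assert neighbor_joining(m) == neighbor_joining(m)

    def test_triangle_violations_tolerated(self):
        d = np.array([
            [0.0, 0.9, 0.05, 0.5],
            [0.9, 0.0, 0.9, 0.5],
            [0.05, 0.9, 0.0, 0.5],
            [0.5, 0.5, 0.5, 0.0],
        ])
        nwk = neighbor_joining(DistanceMatrix(labels=("a", "b", "c", "d"), values=d))
        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_too_few_taxa(self):
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(labels=("a", "b"),
                                            values=np.array([[0, .1], [.1, 0.]])))


class TestAssignFamily:
    def test_candidate_next_to_reference(self, tmp_path):
        rng = np.random.default_rng(3)
        panel = family_panel(rng)
        ref = panel.records[0]
        cand = ProteinRecord(id="cand", seq=ref.seq)
        result = place([cand], panel, k=1)
        assert result.families["cand"] == "crugosa_like"
        assert result.selected == ("cand",)

    def test_mutated_origin_recovered(self):
        rng = np.random.default_rng(13)
        panel = family_panel(rng)
        origin = panel.records[1]  # crugosa_like_1
        cand = ProteinRecord(id="cand", seq=mutate(origin.seq, 0.10, rng))
        result = place([cand], panel, k=1)
        assert result.families["cand"] == "crugosa_like"

    def test_midpoint_between_families_unplaced(self):
        rng = np.random.default_rng(5)
        panel = family_panel(rng)
        # hand-built tree: candidate on the central edge between two pure
        # family subtrees of equal size
        nwk = ("((crugosa_like_0:1,crugosa_like_1:1):1,cand:1,"
               "(yarrowia_0:1,yarrowia_1:1):1);")
        assert assign_family(nwk, panel, "cand") == "unplaced"

    def test_missing_candidate_rejected(self):
        rng = np.random.default_rng(5)
        panel = family_panel(rng)
        nwk = "((crugosa_like_0:1,crugosa_like_1:1):1,yarrowia_0:1,yarrowia_1:1);"
        with pytest.raises(InputError):
            assign_family(nwk, panel, "ghost")

    def test_invariant_to_record_permutation(self):
        rng = np.random.default_rng(31)
        panel = family_panel(rng)
        cands = [
            ProteinRecord(id="c1", seq=mutate(panel.records[0].seq, 0.08, rng)),
            ProteinRecord(id="c2", seq=mutate(panel.records[3].seq, 0.08, rng)),
        ]
        fwd = place(cands, panel, k=2)
        rev = place(cands[::-1], panel, k=2)
        assert fwd.families == rev.families


class TestSelectTopCandidates:
    def test_brute_force_sort_agreement(self):
        rng = np.random.default_rng(19)
        families = {f"c{i}": "crugosa_like" for i in range(8)}
        families["c8"] = "yarrowia"
        dist = {cid: float(rng.uniform(0, 1)) for cid in families}
        got = select_top_candidates(families, dist, k=3)
        expect = tuple(sorted(
            (c for c, f in families.items() if f == "crugosa_like"),
            key=lambda c: (dist[c], c))[:3])
        assert got == expect

    def test_k_larger_than_pool_warns_and_returns_all(self):
        families = {"c1": "crugosa_like", "c2": "yarrowia"}
        dist = {"c1": 0.2, "c2": 0.1}
        with pytest.warns(UserWarning, match="returning all"):
            got = select_top_candidates(families, dist, k=5)
        assert got == ("c1",)

    def test_tie_break_lexicographic(self):
        families = {"b": "crugosa_like", "a": "crugosa_like"}
        dist = {"a": 0.5, "b": 0.5}
        assert select_top_candidates(families, dist, k=1) == ("a",)

    def test_k_must_be_positive(self):
        with pytest.raises(InputError):
            select_top_candidates({}, {}, k=0)
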