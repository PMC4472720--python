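import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsbinning.binning import (
    Binning,
    IncompatibilityGraph,
    are_compatible,
    balanced_color,
    build_incompatibility_graph,
    read_bin_table,
    seed_clique,
    thresholded_splits,
    unweighted_output,
    weight_bins,
    write_bin_table,
)
from wsbinning.simulate import random_binary_topology, set_all_supports
from wsbinning.treeio import (
    LeafSetMismatchError,
    parse_newick,
    splits,
    write_newick,
)

from conftest import enumerate_binary_unrooted


def fully_supported(newick):
    return set_all_supports(parse_newick(newick), 100.0)


class TestAreCompatible:
    def test_identical_topologies_compatible(self):
        t = fully_supported("((a,b),((c,d),e));")
        assert are_compatible(t, t.copy(), 75)

    def test_conflicting_quartets_incompatible(self):
        t1 = fully_supported("((a,b),(c,d));")
        t2 = fully_supported("((a,c),(b,d));")
        assert not are_compatible(t1, t2, 75)

    def test_low_support_conflict_collapses_away(self):
        t1 = set_all_supports(parse_newick("((a,b),(c,d));"), 60.0)
        t2 = set_all_supports(parse_newick("((a,c),(b,d));"), 60.0)
        assert are_compatible(t1, t2, 75)

    def test_threshold_is_inclusive(self):
        # conflict requires both branches at support >= B: exactly B conflicts
        t1 = set_all_supports(parse_newick("((a,b),(c,d));"), 75.0)
        t2 = set_all_supports(parse_newick("((a,c),(b,d));"), 75.0)
        assert not are_compatible(t1, t2, 75)

    def test_leaf_mismatch_raises(self):
        t1 = fully_supported("((a,b),(c,d));")
        t2 = fully_supported("((a,b),(c,e));")
        with pytest.raises(LeafSetMismatchError):
            are_compatible(t1, t2, 50)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_refinement_oracle(self, seed):
        """Brute-force oracle: enumerate every binary tree on <= 6 leaves and
        ask whether one displays all retained splits of both trees."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(5)]
        t1 = random_binary_topology(labels, rng, rooted=False)
        t2 = random_binary_topology(labels, rng, rooted=False)
        for node in itertools.chain(t1.root.postorder(), t2.root.postorder()):
            if not node.is_leaf and node.children:
                node.support = float(rng.choice([40.0, 90.0]))
        t1.root.support = t2.root.support = None
        B = 75.0
        s1 = thresholded_splits(t1, B)
        s2 = thresholded_splits(t2, B)
        oracle = any(
            s1 <= splits(candidate) and s2 <= splits(candidate)
            for candidate in enumerate_binary_unrooted(labels)
        )
        assert are_compatible(t1, t2, B) == oracle


class TestIncompatibilityGraph:
    def test_identical_trees_edgeless(self):
        trees = [fully_supported("((a,b),((c,d),e));") for _ in range(6)]
        g = build_incompatibility_graph(trees, 50)
        assert g.n == 6 and g.edges() == []

    def test_all_low_support_edgeless(self):
        t1 = set_all_supports(parse_newick("((a,b),(c,d));"), 30.0)
        t2 = set_all_supports(parse_newick("((a,c),(b,d));"), 30.0)
        g = build_incompatibility_graph([t1, t2, t1, t2], 50)
        assert g.edges() == []

    def test_k22_structure(self, quartet_ab_cd, quartet_ac_bd):
        trees = [quartet_ab_cd, quartet_ab_cd, quartet_ac_bd, quartet_ac_bd]
        g = build_incompatibility_graph(trees, 75)
        assert set(g.edges()) == {(0, 2), (0, 3), (1, 2), (1, 3)}

    def test_matches_pairwise_oracle(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = [
            set_all_supports(random_binary_topology(labels, rng, rooted=False), 100.0)
            for _ in range(8)
        ]
        g = build_incompatibility_graph(trees, 50)
        for i in range(8):
            for j in range(i + 1, 8):
                assert g.has_edge(i, j) == (not are_compatible(trees[i], trees[j], 50))

    def test_error_carries_gene_index(self):
        bad = parse_newick("((a,b),(c,d),e);")  # missing supports
        good = fully_supported("((a,b),((c,d),e));")
        with pytest.raises(Exception, match="gene 1"):
            build_incompatibility_graph([good, bad], 50)


def graph_from_edges(n, edges):
    g = IncompatibilityGraph(n)
    for i, j in edges:
        g.add_edge(i, j)
    return g


class TestSeedClique:
    def test_edgeless_graph_singleton(self):
        assert seed_clique(graph_from_edges(5, [])) == [0]

    def test_complete_graph_all_vertices(self):
        g = graph_from_edges(5, itertools.combinations(range(5), 2))
        assert sorted(seed_clique(g)) == [0, 1, 2, 3, 4]

    def test_k22_yields_one_edge(self):
        g = graph_from_edges(4, [(0, 2), (0, 3), (1, 2), (1, 3)])
        clique = seed_clique(g)
        # oracle: maximal cliques of K2,2 are exactly its edges
        assert sorted(clique) in [[0, 2], [0, 3], [1, 2], [1, 3]]
        assert clique == [0, 2]  # deterministic under the tie rule

    def test_empty_graph(self):
        assert seed_clique(IncompatibilityGraph(0)) == []

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_returned_set_is_a_clique(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        edges = [e for e in itertools.combinations(range(n), 2) if rng.random() < 0.4]
        g = graph_from_edges(n, edges)
        clique = seed_clique(g)
        for i, j in itertools.combinations(clique, 2):
            assert g.has_edge(i, j)


class TestBalancedColor:
    def test_edgeless_graph_single_bin(self):
        b = balanced_color(graph_from_edges(12, []))
        assert b.bins == [list(range(12))]

    def test_complete_graph_singletons(self):
        g = graph_from_edges(4, itertools.combinations(range(4), 2))
        b = balanced_color(g)
        assert sorted(b.bins) == [[0], [1], [2], [3]]

    def test_determinism_same_seed(self, rng):
        edges = [e for e in itertools.combinations(range(20), 2) if rng.random() < 0.3]
        g = graph_from_edges(20, edges)
        assert balanced_color(g, seed=7).bins == balanced_color(g, seed=7).bins

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_proper_coloring_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        edges = [e for e in itertools.combinations(range(n), 2) if rng.random() < 0.3]
        g = graph_from_edges(n, edges)
        b = balanced_color(g, seed=seed)
        assert sorted(x for bin_ in b.bins for x in bin_) == list(range(n))
        bin_of = b.bin_of()
        for i, j in edges:
            assert bin_of[i] != bin_of[j]

    def test_lemma1_bins_are_topology_classes(self):
        """100 fully supported trees over 20 distinct pairwise-incompatible
        topologies, multiplicity 5 -> exactly the 20 identity classes."""
        rng = np.random.default_rng(123)
        labels = [f"t{i:02d}" for i in range(15)]
        topologies, seen = [], set()
        while len(topologies) < 20:
            t = random_binary_topology(labels, rng, rooted=False)
            sig = splits(t)
            if sig not in seen:
                seen.add(sig)
                topologies.append(set_all_supports(t, 100.0))
        trees = [topologies[i % 20] for i in range(100)]
        g = build_incompatibility_graph(trees, 50)
        b = balanced_color(g, threshold=50, seed=0)
        expected = sorted(sorted(range(k, 100, 20)) for k in range(20))
        assert sorted(b.bins) == expected


class TestOutputs:
    def make_binning(self, sizes):
        bins, start = [], 0
        for s in sizes:
            bins.append(list(range(start, start + s)))
            start += s
        return Binning(bins=bins, threshold=50.0)

    def trees_for(self, binning):
        t = fully_supported("((a,b),((c,d),e));")
        return {i: t for i in range(len(binning.bins))}

    def test_fig1_sizes_give_12_weighted_4_unweighted(self):
        b = self.make_binning([2, 3, 3, 4])
        trees = self.trees_for(b)
        assert len(weight_bins(b, trees)) == 12
        assert len(unweighted_output(b, trees)) == 4

    def test_100_genes_20_bins(self):
        b = self.make_binning([5] * 20)
        trees = self.trees_for(b)
        assert len(weight_bins(b, trees)) == 100
        assert len(unweighted_output(b, trees)) == 20

    def test_singleton_bins_weighted_equals_unweighted(self):
        b = self.make_binning([1, 1, 1])
        trees = {i: fully_supported("((a,b),((c,d),e));") for i in range(3)}
        assert weight_bins(b, trees) == unweighted_output(b, trees)

    def test_replication_counts_follow_bin_sizes(self):
        b = self.make_binning([2, 3])
        t0 = fully_supported("((a,b),((c,d),e));")
        t1 = fully_supported("((a,c),((b,d),e));")
        out = weight_bins(b, {0: t0, 1: t1})
        assert out == [t0, t0, t1, t1, t1]

    def test_missing_supergene_tree_errors(self):
        b = self.make_binning([2, 2])
        with pytest.raises(ValueError, match="bin 1"):
            weight_bins(b, {0: fully_supported("((a,b),((c,d),e));")})

    def test_bin_table_round_trip(self, tmp_path):
        b = self.make_binning([2, 3])
        path = tmp_path / "bins.tsv"
        write_bin_table(b, path)
        assert read_bin_table(path) == {"g0": 0, "g1": 0, "g2": 1, "g3": 1, "g4": 1}


def test_dot_export_lists_all_edges():
    g = graph_from_edges(3, [(0, 1)])
    dot = g.to_dot(["x", "y", "z"])
    assert '"x" -- "y";' in dot and '"z"' in dot
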