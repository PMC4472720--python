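import itertools

import numpy as np
import pytest

from wsbinning.binning import Binning
from wsbinning.simulate import (
    make_caterpillar_species_tree,
    random_binary_topology,
    simulate_gene_trees,
)
from wsbinning.summarize import (
    ReplicateSet,
    assemble_replicates,
    greedy_consensus,
    mlbs,
    rstar_species_tree,
    rstar_summary,
    triplet_counts,
)
from wsbinning.treeio import (
    Bipartition,
    TreeError,
    clades,
    parse_newick,
    splits,
    write_newick,
)

from conftest import enumerate_binary_unrooted


class TestGreedyConsensus:
    def test_identical_inputs_full_support(self):
        t = parse_newick("((a,b),(c,(d,e)));")
        gc = greedy_consensus([t, t.copy(), t.copy()])
        assert splits(gc) == splits(t)
        supports = [n.support for n in gc.internal_edges()]
        assert all(s == 100.0 for s in supports)

    def test_majority_split_retained_with_frequency_support(self):
        from wsbinning.treeio import bipartitions

        t1 = parse_newick("((a,b),(c,(d,e)));")
        t3 = parse_newick("((a,c),(b,(d,e)));")
        gc = greedy_consensus([t1, t1.copy(), t3])
        target = Bipartition({"a", "b"}, t1.leaf_labels)
        supports = {b: s for b, s, _ in bipartitions(gc)}
        assert target in supports
        assert supports[target] == pytest.approx(200 / 3, abs=1e-9)

    def test_disjoint_compatible_splits_union(self):
        from wsbinning.treeio import bipartitions

        # one tree resolves {a,b}, the other {d,e}; supports are 50 each
        t1 = parse_newick("((a,b),c,d,e);")
        t2 = parse_newick("(a,b,c,(d,e));")
        gc = greedy_consensus([t1, t2])
        full = t1.leaf_labels
        expected = {Bipartition({"a", "b"}, full), Bipartition({"d", "e"}, full)}
        assert splits(gc) == expected
        assert sorted(s for _, s, _ in bipartitions(gc)) == [50.0, 50.0]

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(TreeError):
            greedy_consensus([parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));")])

    def test_output_compatible_with_itself(self, rng):
        labels = [f"t{i}" for i in range(7)]
        trees = [random_binary_topology(labels, rng, rooted=False) for _ in range(9)]
        gc = greedy_consensus(trees)
        sp = list(splits(gc))
        for b1, b2 in itertools.combinations(sp, 2):
            assert b1.is_compatible_with(b2)


class TestTripletCounts:
    def test_single_tree_each_triplet_resolved(self):
        t = parse_newick("(((a,b),c),d);", rooted=True)
        dist = triplet_counts([t])
        for tr in dist.triplets():
            assert dist.counts[tr].sum() == 1

    def test_copies_scale_counts_not_frequencies(self):
        t = parse_newick("(((a,b),c),d);", rooted=True)
        one = triplet_counts([t])
        many = triplet_counts([t] * 5)
        for tr in one.triplets():
            assert np.allclose(many.frequencies(tr), one.frequencies(tr))

    def test_three_rotations_uniform(self):
        trees = [
            parse_newick("((a,b),c);", rooted=True),
            parse_newick("((a,c),b);", rooted=True),
            parse_newick("((b,c),a);", rooted=True),
        ]
        dist = triplet_counts(trees)
        assert np.allclose(dist.frequencies(("a", "b", "c")), [1 / 3, 1 / 3, 1 / 3])

    def test_polytomy_counts_as_unresolved(self):
        t = parse_newick("(a,b,c);", rooted=True)
        dist = triplet_counts([t])
        assert dist.unresolved[("a", "b", "c")] == 1
        assert dist.counts[("a", "b", "c")].sum() == 0

    def test_unrooted_input_rejected(self):
        with pytest.raises(TreeError, match="rooted"):
            triplet_counts([parse_newick("((a,b),c,d);")])


class TestRStar:
    def test_exact_recovery_from_single_binary_tree(self, rng):
        for _ in range(10):
            labels = [f"t{i}" for i in range(int(rng.integers(4, 9)))]
            truth = random_binary_topology(labels, rng, rooted=True)
            est = rstar_species_tree(triplet_counts([truth]))
            assert clades(est) == clades(truth)

    def test_all_ties_give_star(self):
        trees = [
            parse_newick("((a,b),c);", rooted=True),
            parse_newick("((a,c),b);", rooted=True),
            parse_newick("((b,c),a);", rooted=True),
        ]
        est = rstar_species_tree(triplet_counts(trees))
        assert clades(est) == frozenset()

    def test_msc_consistency_five_taxa(self):
        model = make_caterpillar_species_tree(5, 0.5)
        gts = simulate_gene_trees(model, 2000, seed=11)
        est = rstar_species_tree(triplet_counts(gts))
        assert clades(est) == clades(model.tree)


class TestMlbs:
    def test_b1_returns_single_summary_tree(self):
        t = parse_newick("(((a,b),c),d);", rooted=True)
        reps = ReplicateSet(replicates=[[t, t, t]])
        out = mlbs(reps, rstar_summary)
        assert clades(out.copy()) if out.rooted else True
        assert splits(out) == splits(t)
        assert all(n.support == 100.0 for n in out.internal_edges())

    def test_identical_replicates_full_support(self):
        t = parse_newick("(((a,b),c),d);", rooted=True)
        reps = ReplicateSet(replicates=[[t, t]] * 5)
        out = mlbs(reps, rstar_summary)
        assert all(n.support == 100.0 for n in out.internal_edges())

    def test_ragged_replicates_rejected(self):
        t = parse_newick("((a,b),c);", rooted=True)
        with pytest.raises(TreeError, match="ragged"):
            ReplicateSet(replicates=[[t, t], [t]])


class TestAssembleReplicates:
    def boots(self, keys, b):
        t = parse_newick("(((a,b),c),d);", rooted=True)
        return {k: [t] * b for k in keys}

    def test_unbinned_width_is_gene_count(self):
        reps = assemble_replicates(self.boots(["g1", "g2", "g3"], 4))
        assert reps.b == 4
        assert all(len(r) == 3 for r in reps.replicates)

    def test_weighted_width_is_total_gene_count(self):
        binning = Binning(bins=[[0, 1], [2, 3, 4], [5, 6, 7], [8, 9, 10, 11]], threshold=50)
        reps = assemble_replicates(self.boots([0, 1, 2, 3], 5), weighting=binning)
        assert all(len(r) == 12 for r in reps.replicates)

    def test_unweighted_binned_width_is_bin_count(self):
        reps = assemble_replicates(self.boots([0, 1, 2, 3], 5))
        assert all(len(r) == 4 for r in reps.replicates)

    def test_unequal_b_rejected(self):
        t = parse_newick("((a,b),c);", rooted=True)
        with pytest.raises(TreeError, match="unequal"):
            assemble_replicates({"g1": [t, t], "g2": [t]})

    def test_replicates_are_indexwise(self):
        t1 = parse_newick("(((a,b),c),d);", rooted=True)
        t2 = parse_newick("(((a,c),b),d);", rooted=True)
        reps = assemble_replicates({"g1": [t1, t2], "g2": [t2, t1]})
        assert [write_newick(t) for t in reps.replicates[0]] == [
            write_newick(t1), write_newick(t2)
        ]
        assert [write_newick(t) for t in reps.replicates[1]] == [
            write_newick(t2), write_newick(t1)
        ]


class TestTheoremMechanisms:
    """Empirical versions of the consistency mechanisms at desk scale."""

    def make_skewed_input(self):
        t_true = parse_newick("((a,b),(c,d));", rooted=True)
        t_alt1 = parse_newick("((a,c),(b,d));", rooted=True)
        t_alt2 = parse_newick("((a,d),(b,c));", rooted=True)
        return t_true, [t_true] * 3 + [t_alt1] + [t_alt2]

    def test_weighted_multiset_recovers_truth(self):
        t_true, multiset = self.make_skewed_input()
        est = rstar_species_tree(triplet_counts(multiset))
        assert splits(est) == splits(t_true)

    def test_unweighted_deduplication_destroys_resolution(self):
        """The 'each topology once' degenerate limit: deduplicating the skewed
        multiset makes every triplet tie, so R* returns the star."""
        t_true, multiset = self.make_skewed_input()
        distinct = [multiset[0], multiset[3], multiset[4]]
        est = rstar_species_tree(triplet_counts(distinct))
        assert splits(est) == frozenset()
        assert splits(rstar_species_tree(triplet_counts(multiset))) == splits(t_true)

    def test_weighted_binned_equals_unbinned_under_lemma1(self):
        """With fully supported true gene trees, weighting reconstitutes the
        input multiset, so the R* trees coincide."""
        from wsbinning.binning import balanced_color, build_incompatibility_graph, weight_bins
        from wsbinning.simulate import set_all_supports

        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]
        pool, seen = [], set()
        while len(pool) < 4:
            t = random_binary_topology(labels, rng, rooted=True)
            if splits(t) not in seen:
                seen.add(splits(t))
                pool.append(set_all_supports(t, 100.0))
        genes = [pool[i % 4] for i in range(10)] + [pool[0]] * 2  # skewed
        graph = build_incompatibility_graph(genes, 50)
        binning = balanced_color(graph, threshold=50, seed=1)
        supergenes = {b: genes[members[0]] for b, members in enumerate(binning.bins)}
        weighted = weight_bins(binning, supergenes)
        direct = rstar_species_tree(triplet_counts(genes))
        via_bins = rstar_species_tree(triplet_counts(weighted))
        assert clades(direct) == clades(via_bins)


class TestRStarExactOnTrueDistributions:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_all_binary_trees_fuzz(self, n, rng):
        labels = [f"t{i}" for i in range(n)]
        for tree in enumerate_binary_unrooted(labels):
            from wsbinning.treeio import root_at_outgroup

            rooted = root_at_outgroup(tree, labels[0])
            est = rstar_species_tree(triplet_counts([rooted]))
            assert clades(est) == clades(rooted)
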