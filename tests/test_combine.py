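"""Consensus and quartet-supertree behavior against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_binary_tree
from corephylo.combine import (
    consensus_with_report,
    gene_tree_quartets,
    majority_rule_extended,
    quartet_score,
    quartet_supertree,
)
from corephylo.errors import TreeError
from corephylo.io import read_newick
from corephylo.metrics import rf_distance
from corephylo.simulate import simulate_species_tree
from corephylo.tree import splits_compatible
from oracles import all_unrooted_topologies, consensus_brute, quartet_score_brute


class TestConsensus:
    def test_identical_trees_reproduce_topology_with_unit_supports(self):
        t = read_newick("((A,B),(C,D),E);")
        out = majority_rule_extended([t.copy(), t.copy(), t.copy()])
        assert rf_distance(out, t) == 0
        assert all(e.support == pytest.approx(1.0) for e in out.nontrivial_splits().values())

    def test_quoted_example_counts(self):
        # split {A,B} in 2 of 3 trees, split {D,E} in 3 of 3
        t1 = read_newick("(((A,B),C),(D,E));")
        t2 = read_newick("(((A,B),C),(D,E));")
        t3 = read_newick("((A,(B,C)),(D,E));")
        out = majority_rule_extended([t1, t2, t3])
        splits = {s: e.support for s, e in out.nontrivial_splits().items()}
        assert splits[frozenset({"D", "E"})] == pytest.approx(1.0)
        # the {A,B} side is stored canonically as its complement {C,D,E}
        assert splits[frozenset({"C", "D", "E"})] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_literal_brute_force_rules(self, trial):
        rng = np.random.default_rng(trial)
        labels = [f"t{i}" for i in range(6)]
        trees = [random_binary_tree(labels, rng) for _ in range(int(rng.integers(3, 8)))]
        ours = majority_rule_extended(trees)
        expected = consensus_brute([t.newick() for t in trees])
        got = {s: e.support for s, e in ours.nontrivial_splits().items()}
        assert set(got) == set(expected)
        for s in got:
            assert got[s] == pytest.approx(expected[s], abs=1e-12)

    def test_supports_are_exact_tree_count_fractions(self, rng):
        labels = [f"t{i}" for i in range(7)]
        trees = [random_binary_tree(labels, rng) for _ in range(5)]
        out = majority_rule_extended(trees)
        for e in out.nontrivial_splits().values():
            assert (e.support * 5) == pytest.approx(round(e.support * 5), abs=1e-12)

    def test_accepted_splits_pairwise_compatible(self, rng):
        labels = [f"t{i}" for i in range(8)]
        trees = [random_binary_tree(labels, rng) for _ in range(7)]
        out = majority_rule_extended(trees)
        taxa = out.leaf_labels
        splits = list(out.nontrivial_splits())
        for a, b in itertools.combinations(splits, 2):
            assert splits_compatible(a, b, taxa)

    def test_unequal_taxon_sets_name_the_offender(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,B),(C,F),E);")
        with pytest.raises(TreeError, match="#2"):
            majority_rule_extended([t1, t2])

    def test_fewer_than_two_trees_rejected(self):
        t = read_newick("((A,B),(C,D),E);")
        with pytest.raises(TreeError):
            majority_rule_extended([t])

    def test_report_rules_labelled(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = [random_binary_tree(labels, rng) for _ in range(5)]
        _, rows = consensus_with_report(trees)
        assert {r.rule for r in rows} <= {"majority", "extension", "rejected"}
        for r in rows:
            if r.frequency > 0.5:
                assert r.rule == "majority"


class TestQuartetSupertree:
    def test_identical_input_trees_are_a_fixed_point(self):
        t = read_newick("(((A,B),C),((D,E),F));")
        out = quartet_supertree([t.copy(), t.copy(), t.copy()], t.leaf_labels)
        assert rf_distance(out, t) == 0
        # every quartet agrees in every tree: score = n_trees * C(6,4)
        tables = [gene_tree_quartets(t) for _ in range(3)]
        assert quartet_score(out, tables) == pytest.approx(3 * math.comb(6, 4))

    @pytest.mark.parametrize("trial", range(8))
    def test_exhaustive_search_matches_brute_force_scorer(self, trial):
        rng = np.random.default_rng(100 + trial)
        labels = [f"t{i}" for i in range(6)]
        trees = []
        for _ in range(7):
            t = random_binary_tree(labels, rng)
            for node in t.root.walk():
                if node.children and node is not t.root:
                    node.support = float(rng.uniform(0.3, 1.0))
            trees.append(t)
        ours = quartet_supertree(trees, labels)
        tables = [gene_tree_quartets(t) for t in trees]
        scores = {
            nw: quartet_score_brute(nw, tables) for nw in all_unrooted_topologies(labels)
        }
        best = max(scores.values())
        assert quartet_score_brute(ours.newick(), tables) == pytest.approx(best, abs=1e-9)

    def test_gene_trees_with_missing_taxa_are_combined(self, rng):
        labels = [f"t{i}" for i in range(6)]
        full = random_binary_tree(labels, rng)
        trees = []
        for drop in labels:
            kept = [x for x in labels if x != drop]
            trees.append(random_binary_tree(kept, rng))
        out = quartet_supertree(trees, labels)
        assert out.leaf_labels == frozenset(labels)

    def test_taxon_in_no_gene_tree_is_an_error(self, rng):
        labels = [f"t{i}" for i in range(5)]
        trees = [random_binary_tree(labels, rng) for _ in range(3)]
        with pytest.raises(TreeError, match="t9"):
            quartet_supertree(trees, labels + ["t9"])

    def test_input_order_invariance_with_unit_weights(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = [random_binary_tree(labels, rng) for _ in range(5)]
        a = quartet_supertree(trees, labels)
        b = quartet_supertree(list(reversed(trees)), labels)
        assert a.newick() == b.newick()

    def test_hill_climbing_path_recovers_strong_signal(self):
        """With exact_limit lowered, the NNI hill climb from the consensus
        seed must still find the dominant topology."""
        truth = simulate_species_tree(7, seed=11)
        trees = [truth.copy() for _ in range(6)]
        out = quartet_supertree(trees, truth.leaf_labels, exact_limit=4)
        assert rf_distance(out, truth) == 0

    def test_supports_are_unit_for_unanimous_quartets(self):
        t = read_newick("(((A,B),C),((D,E),F));")
        out = quartet_supertree([t.copy(), t.copy()], t.leaf_labels)
        for e in out.nontrivial_splits().values():
            assert e.support == pytest.approx(1.0)


def test_enumerator_count_is_correct():
    assert len(all_unrooted_topologies([f"t{i}" for i in range(6)])) == 105
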