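"""Pruning likelihood, branch-length optimisation and gamma-shape fitting."""

import numpy as np
import pytest

from caviarid.likelihood import (Alignment, AlignmentError, fit_alpha,
                                 optimize_branch_lengths, tree_loglik)
from caviarid.phylo import PhyloTree, TreeError
from caviarid.simulate import simulate_alignment
from caviarid.substitution import GTRModel, jukes_cantor

from oracles import enumeration_loglik, random_instance


def test_zero_distance_identical_sequences_jc():
    """With total branch length zero the likelihood is the stationary
    probability of the shared sequence: 100 * ln(1/4) under JC."""
    tree = PhyloTree.from_newick("(X:0.0,Y:0.0);")
    aln = Alignment(["X", "Y"], ["A" * 100, "A" * 100])
    assert tree_loglik(tree, aln, jukes_cantor()) == pytest.approx(
        100 * np.log(0.25))


def test_pruning_matches_enumeration_small_sample(rng):
    """Spot-check pruning against exhaustive state enumeration (the full
    100-instance sweep runs in the acceptance suite)."""
    for _ in range(10):
        tree, aln, model = random_instance(rng)
        assert tree_loglik(tree, aln, model) == pytest.approx(
            enumeration_loglik(tree, aln, model), abs=1e-8)


def test_loglik_invariant_under_rerooting(quartet_tree, quartet_alignment,
                                          gtr_model):
    base = tree_loglik(quartet_tree, quartet_alignment, gtr_model)
    for tip in "ABCD":
        rerooted = quartet_tree.reroot_at(tip)
        assert tree_loglik(rerooted, quartet_alignment,
                           gtr_model) == pytest.approx(base, abs=1e-8)


def test_loglik_invariant_under_tip_reordering(quartet_tree,
                                               quartet_alignment, gtr_model):
    reordered = Alignment(list(reversed(quartet_alignment.names)),
                          list(reversed(quartet_alignment.seqs)))
    assert tree_loglik(quartet_tree, reordered, gtr_model) == pytest.approx(
        tree_loglik(quartet_tree, quartet_alignment, gtr_model), abs=1e-10)


def test_missing_tip_sequence_raises(quartet_tree, gtr_model):
    aln = Alignment(["A", "B", "C"], ["ACGT", "ACGT", "ACGT"])
    with pytest.raises(TreeError):
        tree_loglik(quartet_tree, aln, gtr_model)


def test_nonpositive_loglik_without_allgap_columns(quartet_tree,
                                                   quartet_alignment,
                                                   gtr_model):
    assert tree_loglik(quartet_tree, quartet_alignment, gtr_model) < 0


class TestBranchOptimization:
    @pytest.mark.parametrize("p", [0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
    def test_two_taxon_jc_closed_form(self, p):
        """The fitted pairwise distance equals -(3/4) ln(1 - 4p/3)."""
        n = 1000
        k = round(p * n)
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        tree = PhyloTree.from_newick("(X:0.05,Y:0.05);")
        res = optimize_branch_lengths(tree, Alignment(["X", "Y"], [a, b]),
                                      jukes_cantor())
        expected = -0.75 * np.log(1 - 4 * (k / n) / 3)
        assert res.tree.total_length() == pytest.approx(expected, abs=1e-4)

    def test_loglik_never_decreases(self, quartet_tree, quartet_alignment,
                                    gtr_model):
        before = tree_loglik(quartet_tree, quartet_alignment, gtr_model)
        res = optimize_branch_lengths(quartet_tree, quartet_alignment,
                                      gtr_model)
        assert res.loglik >= before

    def test_reoptimization_is_idempotent(self, quartet_tree,
                                          quartet_alignment, gtr_model, rng):
        """Perturbing optimal lengths and re-optimising recovers the
        log-likelihood."""
        opt = optimize_branch_lengths(quartet_tree, quartet_alignment,
                                      gtr_model)
        perturbed = opt.tree.copy()
        for node in perturbed.branches():
            node.length = max(1e-6, node.length * rng.uniform(0.5, 2.0))
        again = optimize_branch_lengths(perturbed, quartet_alignment,
                                        gtr_model)
        assert again.loglik == pytest.approx(opt.loglik, abs=1e-4)

    def test_optimum_is_fixed_point(self, quartet_tree, quartet_alignment,
                                    gtr_model):
        opt = optimize_branch_lengths(quartet_tree, quartet_alignment,
                                      gtr_model)
        again = optimize_branch_lengths(opt.tree, quartet_alignment,
                                        gtr_model)
        for a, b in zip(opt.tree.branches(), again.tree.branches()):
            assert b.length == pytest.approx(a.length, abs=1e-4)


class TestAlphaFit:
    def test_free_alpha_dominates_fixed(self, quartet_tree, gtr_model):
        aln = simulate_alignment(quartet_tree, gtr_model, 500, 11)
        fit = fit_alpha(quartet_tree, aln, gtr_model)
        for fixed in (0.1, 0.5, 2.0):
            assert fit.loglik >= tree_loglik(
                quartet_tree, aln, gtr_model.with_alpha(fixed)) - 1e-6

    def test_homogeneous_data_hits_upper_bound(self, quartet_tree):
        """Rate-homogeneous data push alpha to the bound, which is flagged."""
        model = GTRModel(freqs=(0.3, 0.2, 0.2, 0.3), rates=(1, 4, 1, 1, 4, 1),
                         alpha=None)
        aln = simulate_alignment(quartet_tree, model, 2000, 5)
        fit = fit_alpha(quartet_tree, aln, model.with_alpha(1.0),
                        bounds=(0.05, 10.0))
        assert fit.at_bound
        assert fit.alpha == pytest.approx(10.0, rel=0.05)


def test_ragged_alignment_rejected():
    with pytest.raises(AlignmentError):
        Alignment(["a", "b"], ["ACGT", "ACG"])
    with pytest.raises(AlignmentError):
        Alignment(["a", "a"], ["ACGT", "ACGT"])
    with pytest.raises(AlignmentError):
        Alignment(["a"], ["ACXT"])
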