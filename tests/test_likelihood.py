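"""Pruning correctness, root invariance, and branch-length fitting."""

import numpy as np
import pytest

from converge.likelihood import (
    LikelihoodError,
    MIN_BRANCH,
    SitewiseLnL,
    optimize_branch_lengths,
    site_log_likelihoods,
    total_log_likelihood,
)
from converge.seqio import ProteinAlignment, tree_from_newick_string
from converge.submodels import build_rate_matrix, transition_probabilities
from converge.synthetic_data import SimulationSpec, random_tree, simulate_alignment


class TestSitewise:
    def test_two_taxon_closed_form(self, wag):
        # a single path of total length t: lnL = log(pi_x * P_xy(t))
        tree = tree_from_newick_string("(a:0.3,b:0.4);")
        aln = ProteinAlignment(["a", "b"], ["AR", "RR"])
        P = transition_probabilities(build_rate_matrix(wag), 0.7, wag.pi)
        expected = np.array(
            [np.log(wag.pi[0] * P[0, 1]), np.log(wag.pi[1] * P[1, 1])]
        )
        got = site_log_likelihoods(aln, tree, wag).values
        assert np.abs(got - expected).max() < 1e-12

    def test_all_gap_column_has_likelihood_one(self, wag_g4):
        tree = tree_from_newick_string("(a:0.1,b:0.2,(c:0.3,d:0.1):0.2);")
        aln = ProteinAlignment(["a", "b", "c", "d"], ["-A", "-R", "XN", "-D"])
        vals = site_log_likelihoods(aln, tree, wag_g4).values
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1] < 0.0

    def test_matches_exhaustive_marginalization(self, wag_g4, exhaustive_oracle):
        rng = np.random.default_rng(5)
        for _ in range(3):
            tree = random_tree(int(rng.integers(3, 6)), seed=int(rng.integers(2**31)))
            aln = simulate_alignment(
                SimulationSpec(tree=tree, model=wag_g4, n_sites=30,
                               seed=int(rng.integers(2**31)))
            )
            mine = site_log_likelihoods(aln, tree, wag_g4).values
            oracle = exhaustive_oracle(aln, tree, wag_g4)
            assert np.abs(mine - oracle).max() < 1e-9

    def test_invariant_category_only_on_constant_sites(self, wag):
        from converge.submodels import load_model

        p_inv = 0.4
        plain = load_model("WAG")
        with_i = load_model("WAG", p_inv=p_inv)
        tree = tree_from_newick_string("(a:0.2,b:0.2,(c:0.2,d:0.2):0.1);")
        # +I rescales the variable class by 1/(1-p_inv): evaluate the plain
        # model on a correspondingly stretched tree to isolate that class
        stretched = tree_from_newick_string(
            "(a:{0},b:{0},(c:{0},d:{0}):{1});".format(0.2 / (1 - p_inv), 0.1 / (1 - p_inv))
        )
        aln = ProteinAlignment(["a", "b", "c", "d"], ["AA", "AR", "AN", "AD"])
        v_scaled = site_log_likelihoods(aln, stretched, plain).values
        v1 = site_log_likelihoods(aln, tree, with_i).values
        # variable site: no invariant-class mass at all
        assert v1[1] == pytest.approx(np.log(1 - p_inv) + v_scaled[1], abs=1e-10)
        # constant site (all alanine): gamma part plus p_inv * pi_A
        expected = np.log((1 - p_inv) * np.exp(v_scaled[0]) + p_inv * wag.pi[0])
        assert v1[0] == pytest.approx(expected, abs=1e-10)

    def test_root_placement_invariance(self, wag_g4):
        tree = random_tree(7, seed=13)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=wag_g4, n_sites=40, seed=17)
        )
        base = site_log_likelihoods(aln, tree, wag_g4).values
        rerooted = tree.copy()
        target = list(rerooted.tree.preorder_internal_node_iter())[-1]
        rerooted.tree.reroot_at_node(target, update_bipartitions=False)
        moved = site_log_likelihoods(aln, rerooted, wag_g4).values
        assert np.abs(base - moved).max() < 1e-10

    def test_leaf_set_mismatch_reported(self, wag):
        tree = tree_from_newick_string("(a:0.1,b:0.1,(c:0.1,e:0.1):0.1);")
        aln = ProteinAlignment(["a", "b", "c", "d"], ["A", "A", "A", "A"])
        with pytest.raises(LikelihoodError, match="'d'.*'e'|'e'.*'d'"):
            site_log_likelihoods(aln, tree, wag)

    def test_positive_sitewise_values_rejected(self):
        with pytest.raises(LikelihoodError):
            SitewiseLnL(np.array([-1.0, 0.5]))


class TestTotals:
    def test_single_site_total(self, wag):
        tree = tree_from_newick_string("(a:0.3,b:0.4);")
        aln = ProteinAlignment(["a", "b"], ["A", "R"])
        s = site_log_likelihoods(aln, tree, wag)
        assert total_log_likelihood(s) == s.values[0]

    def test_duplicated_columns_double_the_total(self, wag_g4):
        tree = tree_from_newick_string("(a:0.1,b:0.2,(c:0.3,d:0.1):0.2);")
        aln = ProteinAlignment(["a", "b", "c", "d"], ["AR", "RR", "NR", "DR"])
        doubled = ProteinAlignment(
            aln.taxa, [row + row for row in aln.rows]
        )
        t1 = total_log_likelihood(site_log_likelihoods(aln, tree, wag_g4))
        t2 = total_log_likelihood(site_log_likelihoods(doubled, tree, wag_g4))
        assert t2 == pytest.approx(2.0 * t1, abs=1e-9)


class TestOptimize:
    def test_identical_sequences_drive_lengths_to_lower_bound(self, wag):
        tree = tree_from_newick_string("(a:0.3,b:0.2,(c:0.4,d:0.1):0.2);")
        aln = ProteinAlignment(["a", "b", "c", "d"], ["ARNDC"] * 4)
        fitted = optimize_branch_lengths(aln, tree, wag, tol=1e-6, xatol=1e-7)
        assert max(fitted.branch_lengths()) < 1e-5
        assert min(fitted.branch_lengths()) >= MIN_BRANCH / 2

    def test_refitting_an_optimum_is_a_fixed_point(self, wag):
        tree = random_tree(5, seed=23)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=wag, n_sites=150, seed=29)
        )
        tol = 1e-5
        once = optimize_branch_lengths(aln, tree, wag, tol=tol)
        twice = optimize_branch_lengths(aln, once, wag, tol=tol)
        assert abs(twice.meta["lnl"] - once.meta["lnl"]) < 10 * tol

    def test_total_lnl_never_decreases(self, wag):
        tree = random_tree(6, seed=31)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=wag, n_sites=80, seed=37)
        )
        before = total_log_likelihood(site_log_likelihoods(aln, tree, wag))
        fitted = optimize_branch_lengths(aln, tree, wag, tol=1e-4)
        assert fitted.meta["lnl"] >= before - 1e-9
        assert fitted.meta["optimization_converged"]

    def test_noise_columns_lower_the_mean_site_likelihood(self, wag):
        tree = random_tree(5, seed=41)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=wag, n_sites=300, seed=43)
        )
        rng = np.random.default_rng(47)
        noise = rng.integers(0, 20, size=(aln.n_taxa, 60))
        noisy = ProteinAlignment.from_codes(
            aln.taxa, np.hstack([aln.codes, noise])
        )
        clean_mean = site_log_likelihoods(aln, tree, wag).values.mean()
        noisy_mean = site_log_likelihoods(noisy, tree, wag).values.mean()
        assert noisy_mean < clean_mean

    def test_invalid_tolerance_rejected(self, wag, quartet_trees):
        aln = ProteinAlignment(["a", "b", "c", "d"], ["A", "R", "N", "D"])
        with pytest.raises(LikelihoodError):
            optimize_branch_lengths(aln, quartet_trees[0], wag, tol=0.0)
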