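"""Rate-matrix structure, pruning correctness and ML behaviour of the codon model."""

import math

import numpy as np
import pytest

import symevol as se
from symevol.codon_model import (
    _IS_NONSYN,
    _IS_TRANSITION,
    _SINGLE_STEP,
    CODONS,
    N_CODONS,
    brute_force_log_likelihood,
    reroot,
)
from symevol.io_formats import BACKGROUND, FOREGROUND, LabeledTree, TreeNode


def two_taxon_tree(t1=0.15, t2=0.15):
    return LabeledTree(
        TreeNode(None, 0.0, BACKGROUND, [TreeNode("s1", t1), TreeNode("s2", t2)])
    )


class TestRateMatrix:
    def test_single_step_only_and_reversibility(self, equal_params):
        rng = np.random.default_rng(0)
        params = se.CodonModelParams(
            float(rng.uniform(1, 5)),
            {"background": float(rng.uniform(0.05, 3))},
            np.asarray(rng.dirichlet(np.ones(N_CODONS))),
        )
        Q = se.build_rate_matrix(params)
        off = ~np.eye(N_CODONS, dtype=bool)
        assert np.all(Q[off & ~_SINGLE_STEP] == 0)
        # detailed balance pi_i q_ij = pi_j q_ji
        flux = params.pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_equal_rates_when_neutral(self):
        params = se.CodonModelParams(1.0, {"background": 1.0}, se.equal_pi())
        Q = se.build_rate_matrix(params)
        vals = Q[_SINGLE_STEP]
        assert np.allclose(vals, vals[0])

    def test_normalised_mean_rate(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            params = se.CodonModelParams(
                float(rng.uniform(0.5, 8)),
                {"background": float(rng.uniform(0.01, 5))},
                np.asarray(rng.dirichlet(np.ones(N_CODONS))),
            )
            Q = se.build_rate_matrix(params)
            assert -float(params.pi @ np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_nonsyn_flux_vanishes_as_omega_to_zero(self):
        for omega, bound in ((0.1, 0.25), (0.01, 0.03), (1e-4, 5e-4)):
            params = se.CodonModelParams(2.0, {"background": omega}, se.equal_pi())
            rho_n, rho_s = se.flux_fractions(params)
            assert rho_n + rho_s == pytest.approx(1.0)
            assert rho_n < bound


class TestTransitionMatrix:
    def test_identity_at_t0(self, equal_params):
        Q = se.build_rate_matrix(equal_params)
        P = se.transition_matrix(Q, 0.0, equal_params.pi)
        assert np.allclose(P, np.eye(N_CODONS), atol=1e-12)

    def test_rows_sum_to_one(self, equal_params):
        Q = se.build_rate_matrix(equal_params)
        for t in (0.01, 0.5, 2.0):
            P = se.transition_matrix(Q, t, equal_params.pi)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0.0

    def test_saturation_reaches_stationarity(self, equal_params):
        Q = se.build_rate_matrix(equal_params)
        P = se.transition_matrix(Q, 50.0, equal_params.pi)
        assert np.abs(P - equal_params.pi[None, :]).max() < 1e-3

    def test_chapman_kolmogorov(self, equal_params):
        Q = se.build_rate_matrix(equal_params)
        rng = np.random.default_rng(5)
        for _ in range(3):
            a, b = rng.uniform(0.05, 1.5, size=2)
            Pa = se.transition_matrix(Q, a, equal_params.pi)
            Pb = se.transition_matrix(Q, b, equal_params.pi)
            Pab = se.transition_matrix(Q, a + b, equal_params.pi)
            assert np.abs(Pa @ Pb - Pab).max() < 1e-8

    def test_negative_time_rejected(self, equal_params):
        Q = se.build_rate_matrix(equal_params)
        with pytest.raises(ValueError):
            se.transition_matrix(Q, -0.1, equal_params.pi)

    def test_stationary_distribution_recovered_from_Q(self, equal_params):
        from symevol.codon_model import stationary_distribution

        Q = se.build_rate_matrix(equal_params)
        pi = stationary_distribution(Q)
        assert np.allclose(pi, equal_params.pi, atol=1e-10)


class TestLikelihood:
    def test_zero_branch_closed_form(self):
        tree = two_taxon_tree(0.0, 0.0)
        seq = "ATGAAA"
        aln = se.CodonAlignment.from_sequences({"s1": seq, "s2": seq})
        params = se.CodonModelParams(2.0, {"background": 0.5}, se.equal_pi())
        expected = sum(math.log(1 / 61) for _ in range(2))
        assert se.log_likelihood(aln, tree, params) == pytest.approx(expected, abs=1e-9)

    def test_pruning_equals_brute_force(self, clade_tree, two_class_params):
        tree = clade_tree.set_foreground_leaf("D")
        aln, _ = se.simulate_codon_alignment(tree, two_class_params, 3, seed=9)
        bf = brute_force_log_likelihood(aln, tree, two_class_params)
        pr = se.log_likelihood(aln, tree, two_class_params)
        assert pr == pytest.approx(bf, abs=1e-9)

    def test_pruning_equals_brute_force_three_taxa(self, two_class_params):
        root = TreeNode(None, 0.0, BACKGROUND, [
            TreeNode("B", 0.3), TreeNode("C", 0.1), TreeNode("D", 0.4, FOREGROUND),
        ])
        tree = LabeledTree(root)
        aln, _ = se.simulate_codon_alignment(tree, two_class_params, 4, seed=11)
        assert se.log_likelihood(aln, tree, two_class_params) == pytest.approx(
            brute_force_log_likelihood(aln, tree, two_class_params), abs=1e-9
        )

    def test_root_invariance(self, clade_tree, equal_params, small_alignment):
        base = se.log_likelihood(small_alignment, clade_tree, equal_params)
        for leaf in ("A", "B", "D"):
            moved = reroot(clade_tree, leaf)
            assert se.log_likelihood(small_alignment, moved, equal_params) == pytest.approx(
                base, abs=1e-9
            )

    def test_taxa_mismatch_rejected(self, clade_tree, equal_params):
        aln = se.CodonAlignment.from_sequences({"X": "ATG", "Y": "ATG"})
        with pytest.raises(ValueError):
            se.log_likelihood(aln, clade_tree, equal_params)


class TestFit:
    def test_two_ratio_nests_one_ratio(self, clade_tree, small_alignment):
        fit0 = se.fit(small_alignment, clade_tree.clear_labels(), "one_ratio",
                      restarts=1, seed=0, pi=se.equal_pi())
        fit1 = se.fit(small_alignment, clade_tree.set_foreground_leaf("D"), "two_ratio",
                      restarts=1, seed=0, pi=se.equal_pi())
        assert fit1.lnL >= fit0.lnL - 1e-6

    def test_one_ratio_recovery_grid(self, clade_tree):
        """Median relative omega error < 15% over a grid of true values."""
        errors = []
        for k, omega in enumerate((0.1, 0.5, 1.0, 2.0)):
            params = se.CodonModelParams(2.0, {"background": omega}, se.equal_pi())
            aln, _ = se.simulate_codon_alignment(clade_tree, params, 2000, seed=50 + k)
            res = se.fit(aln, clade_tree, "one_ratio", restarts=1, seed=k, pi=se.equal_pi())
            errors.append(abs(res.params.omega_by_class["background"] - omega) / omega)
        assert np.median(errors) < 0.15

    def test_degenerate_identical_alignment(self, clade_tree):
        seq = "ATGAAACCC" * 5
        aln = se.CodonAlignment.from_sequences({t: seq for t in "ABCD"})
        res = se.fit(aln, clade_tree, "one_ratio", restarts=1, seed=0)
        assert res.tree_length == 0.0
        assert not res.omega_defined

    def test_two_ratio_requires_foreground(self, clade_tree, small_alignment):
        with pytest.raises(ValueError, match="foreground"):
            se.fit(small_alignment, clade_tree.clear_labels(), "two_ratio")


class TestBranchTest:
    def test_chi2_quantile(self):
        assert se.lrt_pvalue(0.0, 3.841 / 2.0) == pytest.approx(0.05, abs=1e-3)

    def test_equal_likelihoods_give_p_one(self):
        assert se.lrt_pvalue(-100.0, -100.0) == 1.0

    def test_detects_planted_foreground_shift(self, clade_tree, two_class_params):
        tree = clade_tree.set_foreground_leaf("D")
        aln, _ = se.simulate_codon_alignment(tree, two_class_params, 1500, seed=21)
        res = se.branch_test(aln, clade_tree, "D", restarts=1, seed=0, pi=se.equal_pi())
        assert res.p_value < 1e-4
        assert res.direction == "higher"
        assert res.omega_fg > res.omega_bg

    def test_lrt_nonnegative(self, clade_tree, small_alignment):
        res = se.branch_test(small_alignment, clade_tree, "C", restarts=1, seed=3,
                             pi=se.equal_pi())
        assert res.lrt_stat >= -1e-6
        assert 0.0 <= res.p_value <= 1.0


class TestPairwiseDnDs:
    def test_identical_sequences_undefined_ratio(self):
        d = se.pairwise_dnds("ATGAAA", "ATGAAA")
        assert d.dN == 0.0 and d.dS == 0.0 and d.ratio is None

    def test_neutral_recovery(self):
        params = se.CodonModelParams(2.0, {"background": 1.0}, se.equal_pi())
        aln, _ = se.simulate_codon_alignment(two_taxon_tree(), params, 5000, seed=5)
        seqs = aln.to_sequences()
        d = se.pairwise_dnds(seqs["s1"], seqs["s2"], restarts=1, pi=se.equal_pi())
        assert 0.9 <= d.ratio <= 1.1

    def test_synonymous_only_changes(self):
        # third-position changes preserving the amino acid (CTx = Leu, GGx = Gly)
        s1 = "CTTGGTCTCGGA" * 10
        s2 = "CTAGGCCTGGGG" * 10
        d = se.pairwise_dnds(s1, s2, restarts=1)
        assert d.dN == pytest.approx(0.0, abs=5e-3)
        assert d.dS > 0.01
        assert d.ratio == pytest.approx(0.0, abs=5e-3)
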