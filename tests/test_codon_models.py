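import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm
from scipy import integrate, stats

from omegascan.codon_core import STANDARD_CODE, CodonAlignment, equal_frequencies
from omegascan.codon_models import (
    FitOptions,
    LikelihoodEngine,
    SiteClass,
    SiteClassMixture,
    build_rate_matrix,
    discretize_beta,
    fit_model,
    fit_nested_pair,
    make_mixture,
    site_likelihoods,
    transition_matrix,
)
from omegascan.simulator import SimulationSpec, simulate_alignment, three_taxon_tree
from omegascan.tree_topologies import parse_newick


def brute_force_lnL(tree, alignment, kappa, omega, pi, branch_lengths_by_leafset):
    """Independent oracle: sum over all internal-node state assignments,
    with P(t) from scipy's expm rather than the spectral path."""
    Q = build_rate_matrix(kappa, omega, pi).Q
    P = {key: expm(Q * t) for key, t in branch_lengths_by_leafset.items()}
    idx = {c: i for i, c in enumerate(STANDARD_CODE.sense_codons)}
    leaf_codes = {t: [idx[c] for c in row] for t, row in zip(alignment.taxa, alignment.codons)}
    root = tree.root
    internals = [n for n in root.preorder() if not n.is_leaf and n is not root]

    def key_of(node):
        return frozenset(node.leaf_names())

    total = 0.0
    for site in range(alignment.n_codons):
        lik = 0.0
        for assignment in itertools.product(range(61), repeat=len(internals) + 1):
            state = {id(root): assignment[0]}
            for node, s in zip(internals, assignment[1:]):
                state[id(node)] = s
            term = pi.pi[assignment[0]]
            for node in root.preorder():
                if node is root:
                    continue
                s_parent = state[id(node.parent)]
                s_child = (
                    leaf_codes[node.name][site] if node.is_leaf else state[id(node)]
                )
                term *= P[key_of(node)][s_parent, s_child]
            lik += term
        total += np.log(lik)
    return total


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_mean_rate(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        assert np.allclose(Q.Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-(uniform_pi.pi * np.diag(Q.Q)).sum(), 1.0)

    def test_multi_position_changes_have_zero_rate(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        sense = STANDARD_CODE.sense_codons
        for i, j in ((0, 30), (5, 60), (10, 50)):
            ndiff = sum(a != b for a, b in zip(sense[i], sense[j]))
            if ndiff > 1:
                assert Q.Q[i, j] == 0.0

    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.0, uniform_pi)
        sense = STANDARD_CODE.sense_codons
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                if i != j and STANDARD_CODE.translate(a) != STANDARD_CODE.translate(b):
                    assert Q.Q[i, j] == 0.0

    def test_detailed_balance(self, neutral_alignment):
        from omegascan.codon_core import f3x4_frequencies

        pi = f3x4_frequencies(neutral_alignment)
        Q = build_rate_matrix(3.0, 1.7, pi)
        flux = pi.pi[:, None] * Q.Q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_uniform_pi_neutral_kappa1_has_equal_single_change_rates(self, uniform_pi):
        Q = build_rate_matrix(1.0, 1.0, uniform_pi)
        off = Q.Q[Q.Q > 0]
        assert np.allclose(off, off[0])

    def test_invalid_parameters_rejected(self, uniform_pi):
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, uniform_pi)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, -0.1, uniform_pi)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61), atol=1e-10)

    @pytest.mark.parametrize("t", [0.01, 0.5, 3.0, 9.7])
    def test_rows_stochastic(self, uniform_pi, t):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        P = transition_matrix(Q, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_matches_scipy_expm(self, uniform_pi):
        Q = build_rate_matrix(2.5, 0.3, uniform_pi)
        for t in (0.1, 1.0, 4.0):
            assert np.allclose(transition_matrix(Q, t), expm(Q.Q * t), atol=1e-10)

    def test_negative_time_rejected(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)


class TestBetaDiscretization:
    def test_uniform_density_gives_bin_midpoints(self):
        assert np.allclose(discretize_beta(1, 1, 10), np.arange(0.05, 1.0, 0.1))

    @given(
        st.floats(0.1, 20).map(lambda x: round(x, 3)),
        st.floats(0.1, 20).map(lambda x: round(x, 3)),
    )
    def test_category_mean_matches_beta_mean(self, p, q):
        cats = discretize_beta(p, q, 10)
        assert abs(cats.mean() - p / (p + q)) < 1e-3

    def test_categories_match_quadrature_oracle(self):
        p, q, K = 2.0, 5.0, 10
        edges = stats.beta.ppf(np.linspace(0, 1, K + 1), p, q)
        expected = []
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(lambda x: x * stats.beta.pdf(x, p, q), a, b)
            expected.append(val * K)
        assert np.allclose(discretize_beta(p, q, K), expected, atol=1e-7)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            discretize_beta(0, 1, 10)
        with pytest.raises(ValueError):
            discretize_beta(1, 1, 0)


class TestSiteLikelihoods:
    def test_identical_sequences_at_zero_distance_give_log_pi(self, uniform_pi):
        aln = CodonAlignment(taxa=["A", "B"], codons=[["ATG", "AAA"], ["ATG", "AAA"]])
        tree = parse_newick("(A:0,B:0);")
        mix = make_mixture("M0", kappa=2.0, omega=1.0)
        scl, total = site_likelihoods(tree, aln, mix, pi=uniform_pi)
        expected = sum(np.log(uniform_pi.frequency(c)) for c in ["ATG", "AAA"])
        assert np.isclose(total, expected)

    def test_pruning_matches_brute_force_three_taxa(self, star_tree, uniform_pi):
        spec = SimulationSpec(
            tree=star_tree,
            mixture=make_mixture("M0", kappa=2.0, omega=0.7),
            n_codons=5,
            seed=3,
        )
        aln, _ = simulate_alignment(spec)
        mix = make_mixture("M0", kappa=1.8, omega=0.4)
        bl = np.array([0.2, 0.3, 0.1])
        _, total = site_likelihoods(star_tree, aln, mix, branch_lengths=bl, pi=uniform_pi)
        oracle = brute_force_lnL(
            star_tree,
            aln,
            1.8,
            0.4,
            uniform_pi,
            {
                frozenset(["Out"]): 0.2,
                frozenset(["SpeciesA"]): 0.3,
                frozenset(["SpeciesB"]): 0.1,
            },
        )
        assert abs(total - oracle) / abs(oracle) < 1e-8

    def test_duplicated_column_adds_its_site_contribution(self, star_tree, uniform_pi):
        spec = SimulationSpec(
            tree=star_tree,
            mixture=make_mixture("M0", kappa=2.0, omega=1.0),
            n_codons=4,
            seed=9,
        )
        aln, _ = simulate_alignment(spec)
        doubled = CodonAlignment(
            taxa=aln.taxa, codons=[row + [row[0]] for row in aln.codons]
        )
        mix = make_mixture("M0", kappa=2.0, omega=1.0)
        bl = np.full(3, 0.3)
        scl, total = site_likelihoods(star_tree, aln, mix, branch_lengths=bl, pi=uniform_pi)
        _, total2 = site_likelihoods(star_tree, doubled, mix, branch_lengths=bl, pi=uniform_pi)
        assert np.isclose(total2, total + scl[0, 0])

    def test_taxon_reordering_leaves_likelihood_unchanged(self, star_tree, uniform_pi):
        spec = SimulationSpec(
            tree=star_tree,
            mixture=make_mixture("M0", kappa=2.0, omega=1.0),
            n_codons=30,
            seed=4,
        )
        aln, _ = simulate_alignment(spec)
        reordered = CodonAlignment(
            taxa=[aln.taxa[i] for i in (2, 0, 1)],
            codons=[aln.codons[i] for i in (2, 0, 1)],
        )
        mix = make_mixture("M1a", kappa=2.0, p0=0.6, omega0=0.3)
        bl = np.full(3, 0.3)
        _, t1 = site_likelihoods(star_tree, aln, mix, branch_lengths=bl, pi=uniform_pi)
        _, t2 = site_likelihoods(star_tree, reordered, mix, branch_lengths=bl, pi=uniform_pi)
        assert np.isclose(t1, t2)

    def test_taxon_mismatch_raises(self, star_tree, uniform_pi):
        aln = CodonAlignment(taxa=["X", "Y", "Z"], codons=[["ATG"]] * 3)
        with pytest.raises(ValueError, match="name sets differ"):
            LikelihoodEngine(star_tree, aln, pi=uniform_pi)


class TestFitting:
    def test_m0_recovers_neutral_omega(self, star_tree, uniform_pi):
        spec = SimulationSpec(
            tree=star_tree,
            mixture=make_mixture("M0", kappa=2.0, omega=1.0),
            n_codons=500,
            seed=77,
        )
        aln, _ = simulate_alignment(spec)
        fit = fit_model(star_tree, aln, "M0", FitOptions(n_restarts=1), pi=uniform_pi)
        assert 0.8 < fit.mle["omega"] < 1.25
        assert 1.5 < fit.mle["kappa"] < 2.6

    def test_nested_alternatives_never_fit_worse(self, star_tree, uniform_pi, neutral_alignment):
        opts = FitOptions(n_restarts=1)
        for pair in ("M1a/M2a", "M7/M8"):
            null_fit, alt_fit, df = fit_nested_pair(
                star_tree, neutral_alignment, pair, opts, pi=uniform_pi
            )
            assert alt_fit.lnL >= null_fit.lnL - 1e-9
            assert df == 2

    def test_branch_pairs_respect_nesting(self, uniform_pi, neutral_alignment):
        labelled = parse_newick("(Out:0.3 #1,SpeciesA:0.3,SpeciesB:0.3);")
        opts = FitOptions(n_restarts=1)
        for pair, df_expected in (("branch", 1), ("branch-site", 1)):
            null_fit, alt_fit, df = fit_nested_pair(
                labelled, neutral_alignment, pair, opts, pi=uniform_pi
            )
            assert alt_fit.lnL >= null_fit.lnL - 1e-9
            assert df == df_expected
            assert alt_fit.foreground_branch == "Out"

    def test_positive_selection_class_recovered(self, uniform_pi):
        # ~10% of sites at omega 4 on an informative six-taxon tree
        from omegascan.simulator import balanced_tree

        tree = balanced_tree(6, 0.5, seed=2)
        mix = make_mixture("M2a", kappa=2.0, q0=0.6, q1=0.75, omega0=0.1, omega2=4.0)
        assert np.isclose(mix.classes[2].proportion, 0.1)
        spec = SimulationSpec(tree=tree, mixture=mix, n_codons=400, seed=5)
        aln, _ = simulate_alignment(spec)
        fit = fit_model(tree, aln, "M2a", FitOptions(n_restarts=1), pi=uniform_pi)
        assert fit.mle["omega2"] > 1.5
        assert 0.03 < fit.mle["p2"] < 0.25

    def test_branch_model_requires_marked_foreground(self, star_tree, neutral_alignment, uniform_pi):
        with pytest.raises(ValueError, match="foreground"):
            fit_model(star_tree, neutral_alignment, "branch-alt", FitOptions(), pi=uniform_pi)

    def test_mixture_proportions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SiteClassMixture(
                model_name="M0",
                classes=(SiteClass(0.5, 1.0, 1.0),),
                kappa=2.0,
            )

    def test_omega_bias_shrinks_with_sequence_length(self, star_tree, uniform_pi):
        errors = {}
        for n, seed in ((100, 1), (1000, 2)):
            spec = SimulationSpec(
                tree=star_tree,
                mixture=make_mixture("M0", kappa=2.0, omega=0.3),
                n_codons=n,
                seed=seed,
            )
            aln, _ = simulate_alignment(spec)
            fit = fit_model(star_tree, aln, "M0", FitOptions(n_restarts=1), pi=uniform_pi)
            errors[n] = abs(fit.mle["omega"] - 0.3)
        assert errors[1000] < max(errors[100], 0.05)
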