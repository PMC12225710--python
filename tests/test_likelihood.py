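import math

import numpy as np
import pytest
from scipy.stats import multinomial

from stairbayes.likelihood import (
    CompositeLikelihood,
    Conditioning,
    LikelihoodConfig,
    P0Method,
    descendant_prob_table,
    fold_probs,
    lineage_descendant_prob,
    log_composite_likelihood,
    monomorphic_prob,
    polymorphic_probs,
    site_class_probabilities,
)
from stairbayes.sfs_io import SiteFrequencySpectrum


class TestDescendantProbability:
    def test_known_values(self):
        # C(2,0)/C(3,1) = 1/3
        assert lineage_descendant_prob(2, 1, 4) == pytest.approx(1 / 3, abs=1e-15)
        # with all n lineages extant each has exactly one descendant
        for n in (2, 5, 30, 120):
            assert lineage_descendant_prob(n, 1, n) == pytest.approx(1.0, abs=1e-12)
        # violates n-i+1 >= k
        assert lineage_descendant_prob(3, 3, 4) == 0.0
        assert lineage_descendant_prob(2, 0, 4) == 0.0

    @pytest.mark.parametrize("n", [2, 3, 7, 23, 50])
    def test_rows_are_probability_distributions(self, n):
        for k in range(2, n + 1):
            total = sum(lineage_descendant_prob(k, i, n) for i in range(1, n))
            assert abs(total - 1.0) < 1e-12

    def test_table_matches_scalar_function(self):
        n = 11
        table = descendant_prob_table(n)
        for i in range(1, n):
            for k in range(2, n + 1):
                expected = lineage_descendant_prob(k, i, n) / (k - 1)
                assert table[i - 1, k - 2] == pytest.approx(expected, abs=1e-14)


class TestPolymorphicProbs:
    @pytest.mark.parametrize("n", [2, 5, 10, 47, 100])
    def test_constant_theta_gives_fu_closed_form(self, n):
        theta = 1e-3
        p = polymorphic_probs(np.full(n - 1, theta))
        assert np.max(np.abs(p.p - theta / np.arange(1, n))) < 1e-12

    def test_n2_single_term(self):
        p = polymorphic_probs([0.007])
        assert p.p[0] == pytest.approx(0.007, abs=1e-15)

    def test_harmonic_sum_above_one_invalidates(self):
        p = polymorphic_probs(np.full(9, 1.0))
        assert not p.valid


class TestMonomorphicProb:
    def test_no_mutation_limit(self):
        theta = np.full(9, 1e-12)
        assert monomorphic_prob(theta, "complement") == pytest.approx(1.0, abs=1e-10)
        assert monomorphic_prob(theta, "tree_length") == pytest.approx(1.0, abs=1e-10)

    def test_n2_closed_forms(self):
        assert monomorphic_prob([0.01], "complement") == pytest.approx(0.99, abs=1e-15)
        assert monomorphic_prob([0.01], "tree_length") == pytest.approx(
            math.exp(-0.01), abs=1e-15
        )

    def test_methods_agree_to_second_order(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            theta = rng.uniform(1e-5, 5e-3, n - 1)
            S = float(np.sum(theta / (np.arange(2, n + 1) - 1)))
            gap = abs(
                monomorphic_prob(theta, "complement")
                - monomorphic_prob(theta, "tree_length")
            )
            assert gap <= S * S / 2 + 1e-15


class TestFoldProbs:
    def test_definition_n4(self):
        folded = fold_probs([0.1, 0.2, 0.3], 4)
        assert folded == pytest.approx([0.4, 0.2])

    def test_constant_theta_n6(self):
        theta = 2e-3
        p = polymorphic_probs(np.full(5, theta)).p
        folded = fold_probs(p, 6)
        expected = [theta * (1 / i + 1 / (6 - i)) for i in (1, 2)] + [theta / 3]
        assert folded == pytest.approx(expected, abs=1e-15)

    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 9, 10):
            p = rng.dirichlet(np.ones(n - 1)) * 0.1
            assert fold_probs(p, n).sum() == pytest.approx(p.sum(), abs=1e-15)


class TestConditionedProbabilities:
    @pytest.mark.parametrize("p0_method", list(P0Method))
    @pytest.mark.parametrize("conditioning", list(Conditioning))
    @pytest.mark.parametrize("folded", [False, True])
    def test_modeled_classes_sum_to_one(self, p0_method, conditioning, folded):
        rng = np.random.default_rng(3)
        for n in (4, 5, 12):
            theta = rng.uniform(1e-4, 2e-3, n - 1)
            cfg = LikelihoodConfig(p0_method=p0_method, conditioning=conditioning)
            probs = site_class_probabilities(theta, n, cfg, folded=folded)
            assert probs.valid
            assert probs.p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs.p > 0)


class TestCompositeLikelihood:
    def test_matches_independent_multinomial_pmf(self, toy_sfs):
        theta = np.full(3, 0.02)
        # constant theta, n=4: p_i = 0.02/i, p0 = 1 - 0.02*(1 + 1/2 + 1/3)
        p = [1 - 0.02 * 11 / 6, 0.02, 0.01, 0.02 / 3]
        expected = multinomial.logpmf([90, 6, 3, 1], 100, p)
        assert log_composite_likelihood(toy_sfs, theta) == pytest.approx(
            expected, abs=1e-10
        )

    def test_tree_length_p0_matches_renormalized_multinomial(self, toy_sfs):
        theta = np.full(3, 0.02)
        p0 = math.exp(-0.02 * (1 + 1 / 2 + 1 / 3))
        raw = np.array([0.02, 0.01, 0.02 / 3])
        p = np.concatenate([[p0], raw * (1 - p0) / raw.sum()])
        cfg = LikelihoodConfig(p0_method=P0Method.TREE_LENGTH)
        expected = multinomial.logpmf([90, 6, 3, 1], 100, p)
        assert log_composite_likelihood(toy_sfs, theta, cfg) == pytest.approx(
            expected, abs=1e-10
        )

    def test_conditioned_likelihoods_match_renormalized_multinomial(self):
        theta = np.array([0.01, 0.02, 0.004, 0.008, 0.03])
        n = 6
        p = polymorphic_probs(theta).p
        p0 = 1 - p.sum()
        sfs_nomono = SiteFrequencySpectrum(
            n=n, counts=(8, 5, 3, 2, 1), monomorphic_count=None,
            masked_classes={"monomorphic"},
        )
        cfg = LikelihoodConfig(conditioning=Conditioning.NO_MONOMORPHIC)
        expected = multinomial.logpmf([8, 5, 3, 2, 1], 19, p / (1 - p0))
        assert log_composite_likelihood(sfs_nomono, theta, cfg) == pytest.approx(
            expected, abs=1e-10
        )

        sfs_nosing = SiteFrequencySpectrum(
            n=n, counts=(0, 5, 3, 2, 0), monomorphic_count=None,
            masked_classes={"monomorphic", "singletons"},
        )
        cfg = LikelihoodConfig(conditioning=Conditioning.NO_MONO_NO_SINGLETONS)
        denom = 1 - p0 - p[0] - p[-1]
        expected = multinomial.logpmf([5, 3, 2], 10, p[1:-1] / denom)
        assert log_composite_likelihood(sfs_nosing, theta, cfg) == pytest.approx(
            expected, abs=1e-10
        )

    def test_folded_likelihood_matches_folded_multinomial(self):
        theta = np.array([0.01, 0.02, 0.004, 0.008, 0.03])
        pf = fold_probs(polymorphic_probs(theta).p, 6)
        p0 = 1 - pf.sum()
        sfs = SiteFrequencySpectrum(
            n=6, counts=(9, 5, 2), monomorphic_count=984, folded=True
        )
        expected = multinomial.logpmf([984, 9, 5, 2], 1000, np.concatenate([[p0], pf]))
        assert log_composite_likelihood(sfs, theta) == pytest.approx(
            expected, abs=1e-9
        )

    def test_empty_spectrum_has_zero_loglik(self, zero_sfs):
        assert log_composite_likelihood(zero_sfs, np.full(5, 0.01)) == 0.0
        # even for theta violating the sum constraint: no data, no information
        assert log_composite_likelihood(zero_sfs, np.full(5, 1.0)) == 0.0

    def test_invalid_theta_gives_minus_inf(self, toy_sfs):
        assert log_composite_likelihood(toy_sfs, np.full(3, 1.0)) == -np.inf

    def test_nonzero_excluded_count_is_an_error(self):
        sfs = SiteFrequencySpectrum(
            n=6, counts=(8, 5, 3, 2, 1), monomorphic_count=None,
            masked_classes={"monomorphic"},
        )
        cfg = LikelihoodConfig(conditioning=Conditioning.NO_MONO_NO_SINGLETONS)
        with pytest.raises(ValueError, match="singleton"):
            log_composite_likelihood(sfs, np.full(5, 0.01), cfg)

    def test_workspace_equals_reference_implementation(self, constant_sfs):
        sfs, theta, _ = constant_sfs
        rng = np.random.default_rng(9)
        for cfg in (
            LikelihoodConfig(),
            LikelihoodConfig(p0_method=P0Method.TREE_LENGTH),
        ):
            lik = CompositeLikelihood(sfs, cfg)
            for _ in range(10):
                th = theta * rng.uniform(0.5, 2.0, theta.size)
                assert lik(th) == pytest.approx(
                    log_composite_likelihood(sfs, th, cfg), abs=1e-8
                )

    def test_maximized_at_empirical_frequencies(self):
        # multinomial MLE: with the flexible per-interval parameterisation the
        # best constant-theta fit matches the empirical polymorphic fraction
        n = 5
        theta_star = 8e-4
        p_star = np.concatenate(
            [[1 - theta_star * np.sum(1 / np.arange(1, n))],
             theta_star / np.arange(1, n)]
        )
        counts = np.round(p_star * 1e6).astype(int)
        sfs = SiteFrequencySpectrum(
            n=n, counts=tuple(counts[1:]), monomorphic_count=int(counts[0])
        )
        grid = np.linspace(0.2e-4, 40e-4, 300)
        lls = [log_composite_likelihood(sfs, np.full(n - 1, t)) for t in grid]
        best = grid[int(np.argmax(lls))]
        assert best == pytest.approx(theta_star, rel=0.02)
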