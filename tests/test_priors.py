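import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import (
    binom,
    expon,
    gamma as gamma_dist,
    halfcauchy,
    loguniform,
    lognorm,
    norm,
    uniform,
)

from stairbayes.priors import (
    FAMILY_ORDER,
    H,
    PriorFamily,
    PriorSpec,
    default_group_count,
    lognormal_interval_sd,
    log_prior_density,
    make_family,
    sample_prior,
)


class TestConstants:
    def test_order_of_magnitude_sd(self):
        # the lognormal whose 95% central interval spans one decade
        assert lognormal_interval_sd() == pytest.approx(
            math.log(10) / (2 * norm.ppf(0.975)), abs=1e-12
        )
        assert round(lognormal_interval_sd(), 6) == 0.587405
        # sanity: quantile ratio of the implied lognormal is exactly 10
        sd = lognormal_interval_sd()
        assert lognorm.ppf(0.975, sd) / lognorm.ppf(0.025, sd) == pytest.approx(10.0)

    def test_ucln_sigma_hyperprior_mean_is_three_H(self):
        fam = make_family(PriorSpec(PriorFamily.UCLN), 10)
        assert fam.sigma_mean == pytest.approx(3 * 0.587405)


class TestDefaultGroupCount:
    @pytest.mark.parametrize("m,expected", [(20, 10), (2, 1), (3, 2), (1, 1), (5, 2)])
    def test_round_half_even(self, m, expected):
        assert default_group_count(m) == expected


class TestDensities:
    def test_iid_uniform_is_flat(self):
        spec = PriorSpec(PriorFamily.IID_UNIFORM)
        state = sample_prior(spec, 10, 1)
        assert log_prior_density(spec, state) == pytest.approx(9 * math.log(10))
        state.hypers["s"][3] = 0.2  # outside the support
        assert log_prior_density(spec, state) == -np.inf

    def test_gmrf1_matches_scipy_composition(self):
        spec = PriorSpec(PriorFamily.GMRF1, {"xi": 0.5})
        fam = make_family(spec, 4)
        ln_theta = np.array([-6.0, -6.0, -6.0])
        state = {"ln_s": ln_theta}
        # anchor Uniform(0,0.1) + two Normal(0,0.5) increments on the log
        # scale + the log-scale Jacobian for the two non-anchored values
        expected = (
            uniform.logpdf(math.exp(-6.0), 0, 0.1)
            + 2 * norm.logpdf(0.0, 0, 0.5)
            - ln_theta[1:].sum()
        )
        assert fam.log_density(state) == pytest.approx(expected, abs=1e-12)

    def test_gmrf2_second_difference_mean(self):
        spec = PriorSpec(PriorFamily.GMRF2, {"xi": 0.3})
        fam = make_family(spec, 5)
        ln = np.array([-6.0, -5.5, -5.2, -5.3])
        state = {"ln_s": ln}
        expected = (
            uniform.logpdf(math.exp(ln[0]), 0, 0.1)
            + norm.logpdf(ln[1], ln[0], 0.3)
            + norm.logpdf(ln[2], 2 * ln[1] - ln[0], 0.3)
            + norm.logpdf(ln[3], 2 * ln[2] - ln[1], 0.3)
            - ln[1:].sum()
        )
        assert fam.log_density(state) == pytest.approx(expected, abs=1e-12)

    def test_rj_indicator_probability_all_equal(self):
        spec = PriorSpec(PriorFamily.RJ)
        fam = make_family(spec, 6)  # n-1 = 5 intervals, 4 indicators
        state = {
            "values": np.full(5, 0.01),
            "equal": np.ones(4, dtype=bool),
        }
        assert fam.indicator_log_prob(state) == pytest.approx(4 * math.log(0.5))
        assert fam.n_groups(state) == 1
        # total density adds the uniform base for the saturated value vector
        assert fam.log_density(state) == pytest.approx(
            5 * math.log(10) + 4 * math.log(0.5)
        )

    def test_ucln_matches_scipy_composition(self):
        spec = PriorSpec(PriorFamily.UCLN)
        fam = make_family(spec, 5)
        state = {"s": np.array([1e-4, 5e-4, 2e-3, 8e-4]), "mu": 6e-4, "sigma": 1.1}
        expected = (
            loguniform.logpdf(6e-4, 1e-10, 1.0)
            + expon.logpdf(1.1, scale=3 * H)
            + lognorm.logpdf(state["s"], s=1.1, scale=6e-4).sum()
        )
        assert fam.log_density(state) == pytest.approx(expected, rel=1e-10)

    def test_igr_matches_scipy_composition(self):
        spec = PriorSpec(PriorFamily.IGR)
        fam = make_family(spec, 5)
        m, v = 7e-4, 3e-6
        s = np.array([1e-4, 5e-4, 2e-3, 8e-4])
        state = {"ln_s": np.log(s), "m": m, "v": v}
        expected = (
            loguniform.logpdf(m, 1e-10, 1.0)
            + expon.logpdf(v, scale=0.01)
            + gamma_dist.logpdf(s, a=m * m / v, scale=v / m).sum()
        )
        assert fam.log_density(state) == pytest.approx(expected, rel=1e-10)

    def test_hsmrf_matches_scipy_composition(self):
        spec = PriorSpec(PriorFamily.HSMRF1, {"gamma": 0.021})
        fam = make_family(spec, 4)
        ln = np.array([-6.0, -5.9, -6.4])
        local = np.array([0.8, 4.0])
        state = {"ln_s": ln, "local": local}
        expected = (
            uniform.logpdf(math.exp(ln[0]), 0, 0.1)
            + norm.logpdf(ln[1], ln[0], 0.021 * 0.8)
            + norm.logpdf(ln[2], ln[1], 0.021 * 4.0)
            - ln[1:].sum()
            + halfcauchy.logpdf(local).sum()
        )
        assert fam.log_density(state) == pytest.approx(expected, rel=1e-10)

    def test_bsp_autocorrelated_exponential_chain(self):
        spec = PriorSpec(PriorFamily.BSP_GROUPED, {"b": 3})
        fam = make_family(spec, 10)  # L=9 intervals, 3 groups
        state = {
            "group_sizes": np.array([3, 3, 3]),
            "group_values": np.array([0.01, 0.02, 0.005]),
        }
        # C(8,2) = 28 equally likely compositions
        expected = (
            -math.log(28)
            + uniform.logpdf(0.01, 0, 0.1)
            + expon.logpdf(0.02, scale=0.01)
            + expon.logpdf(0.005, scale=0.02)
        )
        assert fam.log_density(state) == pytest.approx(expected, rel=1e-10)

    def test_hsmrf_with_unit_local_scales_nests_gmrf(self):
        # fixing every local scale at 1 reduces the horseshoe field to the
        # Gaussian field with xi = gamma, up to the half-Cauchy factors
        g = 0.05
        hs = make_family(PriorSpec(PriorFamily.HSMRF1, {"gamma": g}), 6)
        gm = make_family(PriorSpec(PriorFamily.GMRF1, {"xi": g}), 6)
        s = np.array([0.01, 0.012, 0.009, 0.011, 0.0105])
        hs_state = {"ln_s": np.log(s), "local": np.ones(4)}
        diff = hs.log_density(hs_state) - gm.log_density({"ln_s": np.log(s)})
        assert diff == pytest.approx(halfcauchy.logpdf(np.ones(4)).sum(), rel=1e-10)

    def test_default_gmrf_scale_spans_one_decade(self):
        n = 20
        fam = make_family(PriorSpec(PriorFamily.GMRF1), n)
        # end-to-end log-ratio SD is sqrt(n-2) * xi = H
        assert math.sqrt(n - 2) * fam.xi0 == pytest.approx(H)


class TestSamplePrior:
    def test_iid_uniform_mean(self):
        spec = PriorSpec(PriorFamily.IID_UNIFORM)
        rng = np.random.default_rng(5)
        draws = np.concatenate(
            [sample_prior(spec, 10, rng).theta for _ in range(12_000)]
        )
        se = 0.1 / math.sqrt(12) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.05) < 3 * se

    def test_rj_group_count_is_binomial(self):
        spec = PriorSpec(PriorFamily.RJ)
        n = 8
        fam = make_family(spec, n)
        rng = np.random.default_rng(6)
        extra_groups = np.array(
            [fam.n_groups(fam.sample_state(rng)) - 1 for _ in range(20_000)]
        )
        # groups - 1 ~ Binomial(n-2, 1 - beta)
        dist = binom(n - 2, 0.5)
        assert abs(extra_groups.mean() - dist.mean()) < 4 * dist.std() / math.sqrt(20_000)
        assert extra_groups.var() == pytest.approx(dist.var(), rel=0.1)

    def test_gmrf1_increment_variance_accumulates(self):
        xi = 0.25
        n = 12
        spec = PriorSpec(PriorFamily.GMRF1, {"xi": xi})
        rng = np.random.default_rng(7)
        spans = []
        for _ in range(20_000):
            theta = sample_prior(spec, n, rng).theta
            spans.append(math.log(theta[0]) - math.log(theta[-1]))
        # theta[-1] = theta_n is the anchored end; n-2 increments of SD xi
        var = np.var(spans)
        assert var == pytest.approx((n - 2) * xi * xi, rel=0.08)

    def test_loguniform_median_is_geometric_mean_of_bounds(self):
        a, b = 1e-10, 1.0
        spec = PriorSpec(PriorFamily.UCLN)
        rng = np.random.default_rng(8)
        mus = np.array(
            [sample_prior(spec, 3, rng).hypers["mu"] for _ in range(20_000)]
        )
        assert np.median(np.log10(mus)) == pytest.approx(
            math.log10(math.sqrt(a * b)), abs=0.15
        )

    @pytest.mark.parametrize("family", FAMILY_ORDER, ids=lambda f: f.value)
    def test_density_finite_at_own_samples(self, family):
        spec = PriorSpec(family)
        rng = np.random.default_rng(11)
        for _ in range(500):
            state = sample_prior(spec, 6, rng)
            assert np.isfinite(log_prior_density(spec, state, n=6))
            assert np.all(state.theta > 0)

    @pytest.mark.parametrize("family", FAMILY_ORDER, ids=lambda f: f.value)
    def test_sampling_is_reproducible(self, family):
        spec = PriorSpec(family)
        a = sample_prior(spec, 8, 99)
        b = sample_prior(spec, 8, 99)
        np.testing.assert_array_equal(a.theta, b.theta)


class TestNormalization:
    """exp(log_prior_density) integrates to 1 on two-dimensional cases."""

    def test_iid_uniform_n3(self):
        fam = make_family(PriorSpec(PriorFamily.IID_UNIFORM), 3)
        val, _ = integrate.dblquad(
            lambda y, x: math.exp(fam.log_density({"s": np.array([x, y])})),
            0, 0.1, 0, 0.1,
        )
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_gmrf1_n3(self):
        fam = make_family(PriorSpec(PriorFamily.GMRF1, {"xi": 0.4}), 3)
        val, _ = integrate.dblquad(
            lambda y, x: math.exp(fam.log_density({"ln_s": np.log([x, y])})),
            1e-12, 0.1,  # anchored coordinate: uniform support
            lambda x: x * 1e-3, lambda x: x * 1e3,  # +-3 decades around x
        )
        assert val == pytest.approx(1.0, rel=1e-3)

    def test_rj_n3_sums_and_integrates_to_one(self):
        fam = make_family(PriorSpec(PriorFamily.RJ), 3)
        total = 0.0
        for flag in (True, False):
            val, _ = integrate.dblquad(
                lambda y, x: math.exp(
                    fam.log_density(
                        {"values": np.array([x, y]),
                         "equal": np.array([flag])}
                    )
                ),
                0, 0.1, 0, 0.1,
            )
            total += val
        assert total == pytest.approx(1.0, rel=1e-6)

    def test_bsp_two_groups_n3(self):
        fam = make_family(PriorSpec(PriorFamily.BSP_GROUPED, {"b": 2}), 3)
        val, _ = integrate.dblquad(
            lambda y, x: math.exp(
                fam.log_density(
                    {"group_sizes": np.array([1, 1]),
                     "group_values": np.array([x, y])}
                )
            ),
            1e-12, 0.1, 0, np.inf,
        )
        assert val == pytest.approx(1.0, rel=1e-6)
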