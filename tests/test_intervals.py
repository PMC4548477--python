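import math

import numpy as np
import pytest
from scipy import stats

from normrisk.model import Scale, summarize_sample
from normrisk.point import EstimatorMethod, NPVariant
from normrisk.bayes import PosteriorDraws, sample_posterior
from normrisk.intervals import (
    BootScheme,
    IntervalEstimate,
    IntervalMethod,
    Sidedness,
    VarianceConvention,
    bca_adjusted_levels,
    bootstrap_ci,
    hpd_from_draws,
    hpd_interval,
    nct_workspace,
    noncentral_t_ci,
    posterior_upper_bound,
    satterthwaite_df,
)


def _draws_from_r(r: np.ndarray) -> PosteriorDraws:
    ones = np.ones_like(r)
    return PosteriorDraws(mu_x=ones, mu_y=ones, var_x=ones, var_y=ones, r=r, seed=0)


class TestHpd:
    def test_normal_draws_recover_equal_tail_quantiles(self):
        z = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hpd_from_draws(z, 0.90)
        assert lo == pytest.approx(-1.6449, abs=0.01)
        assert hi == pytest.approx(1.6449, abs=0.01)

    def test_never_wider_than_equal_tail(self):
        rng = np.random.default_rng(1)
        draws = rng.gamma(2.0, size=5000)  # skewed
        lo, hi = hpd_from_draws(draws, 0.90)
        eq_lo, eq_hi = np.quantile(draws, [0.05, 0.95])
        assert hi - lo <= eq_hi - eq_lo + 1e-12

    def test_skew_hpd_upper_differs_from_percentile(self):
        rng = np.random.default_rng(2)
        r = stats.norm.cdf(rng.normal(-2.0, 0.8, size=20_000))
        draws = _draws_from_r(r)
        hpd = hpd_interval(draws, 0.90, Scale.ORIGINAL)
        pct95 = posterior_upper_bound(draws, 0.95).upper
        assert hpd.upper != pytest.approx(pct95, abs=1e-4)

    def test_construction_scale_matters_and_is_recorded(self):
        rng = np.random.default_rng(3)
        r = stats.norm.cdf(rng.normal(-2.0, 0.8, size=20_000))
        draws = _draws_from_r(r)
        on_probit = hpd_interval(draws, 0.90, Scale.PROBIT)
        on_original = hpd_interval(draws, 0.90, Scale.ORIGINAL)
        assert on_probit.scale_of_construction is Scale.PROBIT
        assert on_probit.upper != pytest.approx(on_original.upper, abs=1e-4)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="too few"):
            hpd_from_draws(np.arange(10.0), 0.95)


class TestPosteriorUpperBound:
    def test_uniform_draws_quantile(self):
        r = np.random.default_rng(4).uniform(size=1_000_000)
        ub = posterior_upper_bound(_draws_from_r(r), 0.95)
        assert ub.upper == pytest.approx(0.95, abs=0.002)
        assert ub.sidedness is Sidedness.UPPER_BOUND and ub.lower == 0.0

    def test_median_matches_point_summary(self, rng):
        from normrisk.bayes import posterior_point
        from normrisk.point import BayesSummary

        s = summarize_sample(rng.normal(size=30))
        draws = sample_posterior(s, s, draws=999, seed=5)
        ub = posterior_upper_bound(draws, 0.5)
        med = posterior_point(draws, BayesSummary.MEDIAN, Scale.ORIGINAL)
        assert ub.upper == pytest.approx(med.prob, abs=1e-12)


class TestSatterthwaite:
    def test_symmetric_case_closed_form(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=20)
        s = summarize_sample(vals)
        assert satterthwaite_df(s, s) == pytest.approx(2 * (20 - 1), abs=1e-9)

    def test_single_sample_limit(self):
        sx = summarize_sample([0.0, 1.0, 2.0, 3.0])
        sy = summarize_sample([5.0, 5.0, 5.0])
        assert satterthwaite_df(sx, sy) == pytest.approx(4 - 1)

    def test_matches_direct_formula(self, rng):
        sx = summarize_sample(rng.normal(0, 1.7, 23))
        sy = summarize_sample(rng.normal(0, 0.4, 9))
        vx, vy = sx.var_unbiased, sy.var_unbiased
        expect = (vx + vy) ** 2 / (vx**2 / 22 + vy**2 / 8)
        assert satterthwaite_df(sx, sy) == pytest.approx(expect, rel=1e-12)

    def test_degenerate_rejected(self):
        s = summarize_sample([1.0, 1.0])
        with pytest.raises(ValueError, match="zero"):
            satterthwaite_df(s, s)


class TestNoncentralT:
    def test_equal_means_give_symmetric_interval(self, rng):
        s = summarize_sample(rng.normal(size=25))
        iv = noncentral_t_ci(s, s, 0.90)
        z_lo, z_hi = stats.norm.ppf([iv.lower, iv.upper])
        assert z_lo == pytest.approx(-z_hi, abs=1e-6)

    def test_inversion_self_consistency(self, case_stats):
        ws = nct_workspace(*case_stats, level=0.90)
        assert stats.nct.cdf(ws.t_obs, ws.df, ws.ncp_lower) == pytest.approx(
            0.95, abs=1e-8
        )
        assert stats.nct.cdf(ws.t_obs, ws.df, ws.ncp_upper) == pytest.approx(
            0.05, abs=1e-8
        )

    def test_upper_bound_nests_two_sided(self, case_stats):
        two = noncentral_t_ci(*case_stats, 0.90)
        ub = noncentral_t_ci(*case_stats, 0.95, Sidedness.UPPER_BOUND)
        assert ub.upper >= two.upper - 1e-12

    def test_variance_convention_changes_interval(self, case_stats):
        a = noncentral_t_ci(*case_stats, 0.90, variance=VarianceConvention.UNBIASED)
        b = noncentral_t_ci(*case_stats, 0.90, variance=VarianceConvention.MLE)
        assert a.upper != b.upper


class TestBootstrap:
    def test_zero_variability_gives_zero_length_interval(self):
        # no overlap: every nonparametric LLS replicate equals 1/(n+2)
        x = np.linspace(-5, -4, 20)
        y = np.linspace(4, 5, 10)
        iv = bootstrap_ci(
            x, y, estimator=EstimatorMethod.NONPARAM, variant=NPVariant.LAPLACE,
            reps=200, seed=0,
        )
        assert iv.degenerate and iv.lower == iv.upper
        assert iv.lower == pytest.approx(1 / 202)

    def test_bca_reduces_to_percentile_without_correction(self):
        # with z0 = a = 0 the adjusted levels equal the nominal levels exactly
        levels = np.array([0.05, 0.5, 0.95])
        assert np.array_equal(bca_adjusted_levels(0.0, 0.0, levels), levels)

    def test_endpoints_are_order_statistics_on_both_scales(self, rng):
        # rank-based quantiles make the interval probit-transform invariant
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 15)
        iv = bootstrap_ci(
            x, y, estimator=EstimatorMethod.QMLE,
            method=IntervalMethod.BOOT_PERCENTILE, reps=500, seed=1,
            keep_replicates=True,
        )
        reps_prob = set(stats.norm.cdf(iv.replicates))
        assert iv.lower in reps_prob and iv.upper in reps_prob

    def test_upper_bound_matches_two_sided_upper_endpoint(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 15)
        kw = dict(
            estimator=EstimatorMethod.QMLE,
            method=IntervalMethod.BOOT_PERCENTILE, seed=2, reps=400,
        )
        two = bootstrap_ci(x, y, level=0.90, **kw)
        one = bootstrap_ci(x, y, level=0.95, sidedness=Sidedness.UPPER_BOUND, **kw)
        assert one.upper == pytest.approx(two.upper, abs=1e-12)
        assert one.lower == 0.0

    def test_nonparam_raw_at_boundary_falls_back_and_clamps(self):
        x = np.linspace(-5, -4, 20)
        y = np.linspace(4, 5, 10)
        iv = bootstrap_ci(
            x, y, estimator=EstimatorMethod.NONPARAM, variant=NPVariant.RAW,
            reps=200, seed=3,
        )
        # all replicates at probit -inf: degenerate zero-risk interval
        assert iv.degenerate and iv.lower == 0.0 and iv.upper == 0.0

    def test_schemes_both_run_and_respect_bounds(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 8)
        for scheme in BootScheme:
            for method in (IntervalMethod.BOOT_BCA, IntervalMethod.BOOT_PERCENTILE):
                iv = bootstrap_ci(
                    x, y, estimator=EstimatorMethod.QMLE, scheme=scheme,
                    method=method, reps=300, seed=4,
                )
                assert 0.0 <= iv.lower <= iv.upper <= 1.0

    def test_too_few_reps_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            bootstrap_ci(rng.normal(size=10), rng.normal(size=10), reps=50)


class TestIntervalEstimate:
    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError, match="endpoints"):
            IntervalEstimate(
                lower=0.8, upper=0.2, level=0.9,
                sidedness=Sidedness.TWO_SIDED, method=IntervalMethod.HPD,
                scale_of_construction=Scale.PROBIT,
            )

    def test_degenerate_flag_mirrors_equality(self):
        with pytest.raises(ValueError, match="degenerate"):
            IntervalEstimate(
                lower=0.2, upper=0.2, level=0.9,
                sidedness=Sidedness.TWO_SIDED, method=IntervalMethod.HPD,
                scale_of_construction=Scale.PROBIT, degenerate=False,
            )
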