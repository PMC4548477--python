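import math

import numpy as np
import pytest

from normrisk.model import Scale, true_risk
from normrisk.intervals import IntervalEstimate, IntervalMethod, Sidedness
from normrisk.simulate import (
    DEFAULT_RISK_GRID,
    ScenarioSpec,
    SimulationPlan,
    coverage_and_length,
    make_scenarios,
    performance_measures,
    required_reps,
    results_to_frame,
    run_scenario,
)


def _plan(B):
    return SimulationPlan(z=1.0, pilot_sd=1.0, pilot_delta=1.0, B=B)


def _interval(lo, hi, sidedness=Sidedness.TWO_SIDED):
    return IntervalEstimate(
        lower=lo, upper=hi, level=0.9, sidedness=sidedness,
        method=IntervalMethod.NONCENTRAL_T, scale_of_construction=Scale.PROBIT,
        degenerate=(lo == hi),
    )


class TestRequiredReps:
    def test_pilot_formula_worked_example(self):
        raw, B = required_reps(1.96, 0.0719496, 0.002107476)
        assert round(raw, 2) == 4477.58
        assert B == 4500
        _, B500 = required_reps(
            1.96, 0.0719496, 0.002107476, rounding="multiple_of_500"
        )
        assert B500 == 4500

    def test_quadratic_scaling_in_delta(self):
        raw1, _ = required_reps(2.0, 1.0, 0.1)
        raw2, _ = required_reps(2.0, 1.0, 0.2)
        assert raw1 == pytest.approx(4 * raw2)

    def test_identity_inputs(self):
        raw, B = required_reps(1.0, 1.0, 1.0, rounding="ceil")
        assert raw == 1.0 and B == 1

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            required_reps(1.96, 0.1, 0.0)


class TestMakeScenarios:
    def test_half_risk_means_coincide(self):
        spec = make_scenarios(
            n_x_grid=[5], n_y_grid=[2], sigma_ratios=[1.0], risks=[0.5]
        )[0]
        assert spec.params.mu_x == pytest.approx(spec.params.mu_y, abs=1e-12)

    def test_grid_cardinality(self):
        specs = make_scenarios(master_seed=1)
        assert len(specs) == 2 * 5 * 3 * len(DEFAULT_RISK_GRID)

    def test_roundtrip_true_risk(self):
        for spec in make_scenarios(
            n_x_grid=[100], n_y_grid=[12], sigma_ratios=[0.2, 5.0],
            risks=[1e-7, 0.01, 0.5],
        ):
            assert true_risk(spec.params).prob == pytest.approx(
                spec.true_r, abs=1e-12
            )

    def test_out_of_grid_risk_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            make_scenarios(n_x_grid=[5], n_y_grid=[2], sigma_ratios=[1.0], risks=[0.7])

    def test_seeds_deterministic_in_master_seed(self):
        a = make_scenarios(master_seed=5)
        b = make_scenarios(master_seed=5)
        c = make_scenarios(master_seed=6)
        assert [s.seed for s in a] == [s.seed for s in b]
        assert [s.seed for s in a] != [s.seed for s in c]


class TestPerformanceMeasures:
    def test_constant_estimates(self):
        ps = performance_measures([1.5, 1.5, 1.5], true_probit=1.0)
        assert ps.bias == pytest.approx(0.5)
        assert ps.sd == 0.0
        assert ps.rmse == pytest.approx(abs(ps.bias))

    def test_rmse_identity_on_random_vectors(self, rng):
        z = rng.normal(size=500)
        ps = performance_measures(z, true_probit=-1.0)
        assert ps.rmse**2 == pytest.approx(ps.bias**2 + ps.sd**2, abs=1e-10)

    def test_matches_two_pass_oracle(self, rng):
        z = rng.normal(2.0, 0.3, size=400)
        truth = 1.9
        ps = performance_measures(z, truth)
        mean = sum(z) / len(z)
        sd = math.sqrt(sum((v - mean) ** 2 for v in z) / len(z))
        assert ps.probit_mean == pytest.approx(mean, rel=1e-12)
        assert ps.bias == pytest.approx(mean - truth, rel=1e-9)
        assert ps.sd == pytest.approx(sd, rel=1e-12)

    def test_nonfinite_estimates_yield_undefined_summary(self):
        ps = performance_measures([0.1, -math.inf, 0.2], true_probit=0.0)
        assert not ps.defined and ps.n_nonfinite == 1
        assert math.isnan(ps.rmse)


class TestCoverageAndLength:
    def test_no_containment(self):
        ivs = [_interval(0.6, 0.9)] * 5
        cs = coverage_and_length(ivs, true_r=0.1)
        assert cs.coverage == 0.0

    def test_full_interval_always_covers_with_infinite_length(self):
        ivs = [_interval(0.0, 1.0)] * 5
        cs = coverage_and_length(ivs, true_r=0.1)
        assert cs.coverage == 1.0
        assert cs.n_infinite_length == 5

    def test_relative_length_undefined_at_half(self):
        ivs = [_interval(0.4, 0.6)] * 3
        cs = coverage_and_length(ivs, true_r=0.5)
        assert math.isnan(cs.relative_median_length)
        assert cs.median_length_probit > 0

    def test_upper_bound_summary_uses_bound_minus_truth(self):
        from scipy.stats import norm

        ivs = [_interval(0.0, 0.3, Sidedness.UPPER_BOUND)] * 3
        cs = coverage_and_length(ivs, true_r=0.1)
        assert cs.coverage == 1.0
        expect = norm.ppf(0.3) - norm.ppf(0.1)
        assert cs.median_length_probit == pytest.approx(expect)


class TestRunScenario:
    @pytest.fixture(scope="class")
    def spec(self):
        return make_scenarios(
            n_x_grid=[20], n_y_grid=[5], sigma_ratios=[1.0], risks=[0.1],
            master_seed=2,
        )[0]

    def test_oracle_estimator_has_zero_error(self, spec):
        oracle = lambda ctx: true_risk(ctx.spec.params).probit
        res = run_scenario(
            spec, _plan(20), estimators={"oracle": oracle}, interval_methods={}
        )
        ps = res.point["oracle"]
        assert ps.bias == 0.0 and ps.sd == 0.0 and ps.rmse == 0.0

    def test_full_interval_method_has_unit_coverage(self, spec):
        full = lambda ctx: {
            "two_sided": _interval(0.0, 1.0),
            "upper": _interval(0.0, 1.0, Sidedness.UPPER_BOUND),
        }
        res = run_scenario(
            spec, _plan(20), estimators={}, interval_methods={"full": full}
        )
        assert res.two_sided["full"].coverage == 1.0
        assert res.upper["full"].coverage == 1.0

    def test_reproducible_and_order_independent(self, spec):
        kw = dict(draws=200, boot_reps=100)
        full = run_scenario(spec, _plan(10), **kw)
        again = run_scenario(spec, _plan(10), **kw)
        assert full.point["qmle"] == again.point["qmle"]
        assert full.two_sided["hpd"] == again.two_sided["hpd"]
        # running a subset must not change the subset's results
        from normrisk.simulate import DEFAULT_ESTIMATORS, DEFAULT_INTERVALS

        sub = run_scenario(
            spec, _plan(10),
            estimators={"qmle": DEFAULT_ESTIMATORS["qmle"]},
            interval_methods={"hpd": DEFAULT_INTERVALS["hpd"]},
            **kw,
        )
        assert sub.point["qmle"] == full.point["qmle"]
        assert sub.two_sided["hpd"] == full.two_sided["hpd"]

    def test_failing_method_above_threshold_raises(self, spec):
        def broken(ctx):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="broken"):
            run_scenario(
                spec, _plan(10), estimators={"broken": broken}, interval_methods={}
            )

    def test_tidy_frame_layout(self, spec):
        res = run_scenario(spec, _plan(10), draws=200, boot_reps=100)
        frame = results_to_frame([res])
        assert {"kind", "method", "true_r", "coverage", "rmse"} <= set(frame.columns)
        assert (frame["n_reps"] == 10).all()
        assert set(frame["kind"]) == {"point", "two_sided", "upper"}


class TestSimulationPlan:
    def test_b_below_pilot_requirement_rejected(self):
        with pytest.raises(ValueError, match="below"):
            SimulationPlan(z=1.96, pilot_sd=0.0719496, pilot_delta=0.002107476, B=4000)
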