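"""Monte-Carlo simulation study of the risk estimators.

The study design follows the structure of probabilistic environmental risk
assessment practice: a grid of scenarios over exposure sample size n_x,
effect sample size n_y, the sd ratio sigma_y / sigma_x and the true risk R,
with every estimator and interval method evaluated on the *same* simulated
dataset within each replicate, so that differences between methods are not
confounded with sampling noise.

Performance is measured on the probit scale: mean, bias, empirical
(population-divisor) standard deviation and RMSE of the probit estimates;
for intervals, the coverage probability, the median probit-scale interval
length and its value relative to |probit(R)| (undefined at R = 0.5, where
probit(R) = 0), and for upper bounds the median difference between the
bound and the true probit(R), again also relative to |probit(R)|.

Replicate counts can be derived from a pilot run with
:func:`required_reps`: B = (z * sd / delta)^2, rounded up per policy.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    NormalNormalParams,
    Scale,
    probit_transform,
    summarize_sample,
    true_risk,
)
from .point import (
    BayesSummary,
    EstimatorMethod,
    NPVariant,
    estimate_mle,
    estimate_np,
    estimate_qmle,
)
from .bayes import posterior_point, sample_posterior
from .intervals import (
    IntervalEstimate,
    IntervalMethod,
    Sidedness,
    VarianceConvention,
    bootstrap_ci,
    hpd_interval,
    noncentral_t_ci,
    posterior_upper_bound,
)

__all__ = [
    "DEFAULT_RISK_GRID",
    "SIGMA_RATIOS",
    "ScenarioSpec",
    "SimulationPlan",
    "PerformanceSummary",
    "CoverageLengthSummary",
    "ScenarioResult",
    "required_reps",
    "make_scenarios",
    "performance_measures",
    "coverage_and_length",
    "run_scenario",
    "results_to_frame",
]

#: Default grid of true risks, spanning the extremely small values relevant
#: to environmental risk assessment up to the no-separation case R = 0.5.
DEFAULT_RISK_GRID = (1e-14, 1e-10, 1e-7, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.25, 0.5)

#: Named sd-ratio scenarios sigma_y / sigma_x.
SIGMA_RATIOS = {"equal": 1.0, "one_fifth": 0.2, "five": 5.0}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid, with derived true parameters."""

    n_x: int
    n_y: int
    sigma_ratio: float
    true_r: float
    params: NormalNormalParams
    seed: int

    def __post_init__(self) -> None:
        rt = true_risk(self.params).prob
        if abs(rt - self.true_r) > 1e-12:
            raise ValueError(
                f"params imply R={rt!r}, but true_r={self.true_r!r}"
            )


@dataclass(frozen=True)
class SimulationPlan:
    """Number of replicates B together with the pilot inputs that set it."""

    z: float
    pilot_sd: float
    pilot_delta: float
    B: int

    def __post_init__(self) -> None:
        raw = (self.z * self.pilot_sd / self.pilot_delta) ** 2
        if self.B < raw - 1e-9:
            raise ValueError(f"B={self.B} is below the pilot requirement {raw:.2f}")


@dataclass(frozen=True)
class PerformanceSummary:
    """Probit-scale mean/bias/sd/rmse of a point estimator over replicates.

    If any replicate estimate is non-finite on the probit scale (the
    non-parametric RAW estimator at a boundary) the summary is undefined:
    the statistics are NaN and ``n_nonfinite`` carries the count, rather
    than silently dropping the offending replicates.
    """

    probit_mean: float
    bias: float
    sd: float
    rmse: float
    n_reps: int
    n_nonfinite: int = 0

    @property
    def defined(self) -> bool:
        return self.n_nonfinite == 0


@dataclass(frozen=True)
class CoverageLengthSummary:
    """Coverage and length summary for one interval method."""

    sidedness: Sidedness
    coverage: float
    median_length_probit: float
    relative_median_length: float  # NaN when undefined (true R = 0.5)
    n: int
    n_degenerate: int
    n_infinite_length: int


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    n_reps: int
    point: dict
    quantiles: dict  # estimator -> (q0.025, median, q0.975) of probit estimates
    two_sided: dict
    upper: dict
    error_counts: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        """Tidy rows (one per estimator / interval method) for CSV output."""
        base = dict(
            n_x=self.spec.n_x,
            n_y=self.spec.n_y,
            sigma_ratio=self.spec.sigma_ratio,
            true_r=self.spec.true_r,
            seed=self.spec.seed,
            n_reps=self.n_reps,
        )
        rows = []
        for name, ps in self.point.items():
            q = self.quantiles[name]
            rows.append(
                base
                | dict(
                    kind="point",
                    method=name,
                    probit_mean=ps.probit_mean,
                    bias=ps.bias,
                    sd=ps.sd,
                    rmse=ps.rmse,
                    n_nonfinite=ps.n_nonfinite,
                    q025=q[0],
                    q50=q[1],
                    q975=q[2],
                )
            )
        for kind, summaries in (("two_sided", self.two_sided), ("upper", self.upper)):
            for name, cs in summaries.items():
                rows.append(
                    base
                    | dict(
                        kind=kind,
                        method=name,
                        coverage=cs.coverage,
                        median_length_probit=cs.median_length_probit,
                        relative_median_length=cs.relative_median_length,
                        n_degenerate=cs.n_degenerate,
                        n_infinite_length=cs.n_infinite_length,
                    )
                )
        return rows


def required_reps(
    z: float, sd: float, delta: float, rounding: str = "multiple_of_100"
) -> tuple[float, int]:
    """Pilot-based number of Monte-Carlo replicates.

    raw = (z * sd / delta)^2; B rounds raw up according to ``rounding``:
    ``"multiple_of_100"`` (default), ``"multiple_of_500"`` or ``"ceil"``.
    Returns (raw, B).
    """
    if z <= 0 or sd <= 0:
        raise ValueError("z and sd must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")
    raw = (z * sd / delta) ** 2
    if rounding == "multiple_of_100":
        B = int(math.ceil(raw / 100.0)) * 100
    elif rounding == "multiple_of_500":
        B = int(math.ceil(raw / 500.0)) * 500
    elif rounding == "ceil":
        B = int(math.ceil(raw))
    else:
        raise ValueError(f"unknown rounding policy {rounding!r}")
    return raw, B


def _scenario_seed(master_seed: int, index: int) -> int:
    """Deterministic per-scenario seed derived from a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def make_scenarios(
    n_x_grid: Sequence[int] = (5, 100),
    n_y_grid: Sequence[int] = (2, 5, 12, 20, 100),
    sigma_ratios: Sequence[float] = (1.0, 0.2, 5.0),
    risks: Sequence[float] = DEFAULT_RISK_GRID,
    master_seed: int = 0,
) -> list[ScenarioSpec]:
    """Cartesian scenario grid, anchored by location-scale invariance.

    Each scenario fixes mu_y = 0 and sigma_x = 1 (R depends only on the
    mean difference and summed variance), sets sigma_y by the ratio and
    solves mu_x = probit(R) * sqrt(sigma_x^2 + sigma_y^2) for the target
    risk.  Per-scenario seeds derive deterministically from the master
    seed and the scenario index.
    """
    specs = []
    index = 0
    for r in risks:
        if not (0.0 < r <= 0.5):
            warnings.warn(
                f"risk {r} outside the (0, 0.5] study grid", stacklevel=2
            )
    for n_x in n_x_grid:
        for n_y in n_y_grid:
            for ratio in sigma_ratios:
                for r in risks:
                    sigma_y = float(ratio)
                    mu_x = probit_transform(r) * math.hypot(1.0, sigma_y)
                    params = NormalNormalParams(
                        mu_x=mu_x, mu_y=0.0, sigma_x=1.0, sigma_y=sigma_y
                    )
                    specs.append(
                        ScenarioSpec(
                            n_x=int(n_x),
                            n_y=int(n_y),
                            sigma_ratio=float(ratio),
                            true_r=float(r),
                            params=params,
                            seed=_scenario_seed(master_seed, index),
                        )
                    )
                    index += 1
    return specs


def performance_measures(
    probit_estimates: Sequence[float], true_probit: float
) -> PerformanceSummary:
    """Probit-scale performance measures over replicates.

    mean, bias = mean - true_probit, empirical sd with population divisor
    (the number of replicates) and rmse = sqrt(bias^2 + sd^2).  Any
    non-finite estimate makes the summary undefined (NaN statistics with
    the non-finite count reported).
    """
    z = np.asarray(probit_estimates, dtype=float)
    n = int(z.size)
    if n == 0:
        raise ValueError("no estimates")
    n_bad = int(np.sum(~np.isfinite(z)))
    if n_bad:
        return PerformanceSummary(
            probit_mean=math.nan,
            bias=math.nan,
            sd=math.nan,
            rmse=math.nan,
            n_reps=n,
            n_nonfinite=n_bad,
        )
    mean = float(z.mean())
    bias = mean - true_probit
    sd = float(z.std(ddof=0))
    return PerformanceSummary(
        probit_mean=mean,
        bias=bias,
        sd=sd,
        rmse=math.hypot(bias, sd),
        n_reps=n,
    )


def coverage_and_length(
    intervals: Sequence[IntervalEstimate], true_r: float
) -> CoverageLengthSummary:
    """Coverage and median probit length of a homogeneous interval list.

    Containment is endpoint-inclusive.  For two-sided intervals the length
    is upper - lower on the probit scale; for upper bounds it is the
    difference between the bound and the true probit(R).  Relative values
    divide by |probit(R)| and are NaN (undefined) at R = 0.5.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval list")
    sidednesses = {iv.sidedness for iv in intervals}
    if len(sidednesses) != 1:
        raise ValueError("mixed sidedness in interval list")
    sidedness = sidednesses.pop()
    true_z = probit_transform(true_r)
    covered = np.array([iv.contains(true_r) for iv in intervals])
    if sidedness is Sidedness.TWO_SIDED:
        lengths = np.array([iv.length_probit for iv in intervals])
    else:
        uppers = np.array([probit_transform(iv.upper) for iv in intervals])
        lengths = uppers - true_z
    med = float(np.median(lengths))
    denom = abs(true_z)
    rel = med / denom if denom > 0 else math.nan
    return CoverageLengthSummary(
        sidedness=sidedness,
        coverage=float(covered.mean()),
        median_length_probit=med,
        relative_median_length=rel,
        n=len(intervals),
        n_degenerate=int(sum(iv.degenerate for iv in intervals)),
        n_infinite_length=int(np.sum(~np.isfinite(lengths))),
    )


# --------------------------------------------------------------------------
# Replicate execution


class ReplicateContext:
    """Per-replicate shared state handed to estimator/interval callables.

    Sample statistics are computed once; the Bayesian posterior is sampled
    lazily on first request (with a replicate-specific seed) so replicates
    that never touch it cost nothing, and per-method RNG streams are
    derived from (scenario seed, replicate index, method name) so results
    do not depend on the order in which methods are evaluated.
    """

    def __init__(self, spec, rep_index, x, y, draws, boot_reps, level, upper_prob):
        self.spec = spec
        self.rep_index = rep_index
        self.x = x
        self.y = y
        self.stats_x = summarize_sample(x, "exposure sample")
        self.stats_y = summarize_sample(y, "effect sample")
        self.draws = draws
        self.boot_reps = boot_reps
        self.level = level
        self.upper_prob = upper_prob
        self._posterior = None

    def method_seed(self, name: str) -> np.random.SeedSequence:
        tag = zlib.crc32(name.encode())
        return np.random.SeedSequence([self.spec.seed, self.rep_index, tag])

    def method_rng(self, name: str) -> np.random.Generator:
        return np.random.default_rng(self.method_seed(name))

    def posterior(self):
        if self._posterior is None:
            self._posterior = sample_posterior(
                self.stats_x,
                self.stats_y,
                draws=self.draws,
                seed=self.rep_index,
                rng=self.method_rng("bayes_posterior"),
            )
        return self._posterior


def _est_mle(ctx: ReplicateContext) -> float:
    return estimate_mle(ctx.stats_x, ctx.stats_y).probit


def _est_qmle(ctx: ReplicateContext) -> float:
    return estimate_qmle(ctx.stats_x, ctx.stats_y).probit


def _est_bayes(ctx: ReplicateContext) -> float:
    return posterior_point(ctx.posterior(), BayesSummary.MEDIAN, Scale.PROBIT).probit


def _est_np_lls(ctx: ReplicateContext) -> float:
    return estimate_np(ctx.x, ctx.y, NPVariant.LAPLACE).probit


def _est_np_raw(ctx: ReplicateContext) -> float:
    return estimate_np(ctx.x, ctx.y, NPVariant.RAW).probit


DEFAULT_ESTIMATORS: Mapping[str, Callable[[ReplicateContext], float]] = {
    "mle": _est_mle,
    "qmle": _est_qmle,
    "bayes": _est_bayes,
    "np_lls": _est_np_lls,
    "np_raw": _est_np_raw,
}


def _upper_from_two_sided(two: IntervalEstimate, prob: float) -> IntervalEstimate:
    """Reuse a percentile-type two-sided interval's upper endpoint as the
    one-sided bound at level (1 + level)/2."""
    return IntervalEstimate(
        lower=0.0,
        upper=two.upper,
        level=prob,
        sidedness=Sidedness.UPPER_BOUND,
        method=two.method,
        scale_of_construction=two.scale_of_construction,
        degenerate=(two.upper == 0.0),
        fell_back_from_bca=two.fell_back_from_bca,
        n_failed=two.n_failed,
    )


def _iv_nct(ctx: ReplicateContext, variance: VarianceConvention):
    two = noncentral_t_ci(
        ctx.stats_x, ctx.stats_y, level=ctx.level, variance=variance
    )
    up = noncentral_t_ci(
        ctx.stats_x,
        ctx.stats_y,
        level=ctx.upper_prob,
        sidedness=Sidedness.UPPER_BOUND,
        variance=variance,
    )
    return {"two_sided": two, "upper": up}


def _iv_nct_qmle(ctx):
    return _iv_nct(ctx, VarianceConvention.UNBIASED)


def _iv_nct_mle(ctx):
    return _iv_nct(ctx, VarianceConvention.MLE)


def _iv_boot_bca(ctx: ReplicateContext, estimator: EstimatorMethod, name: str):
    two = bootstrap_ci(
        ctx.x,
        ctx.y,
        estimator=estimator,
        reps=ctx.boot_reps,
        level=ctx.level,
        rng=ctx.method_rng(name),
    )
    return {"two_sided": two, "upper": _upper_from_two_sided(two, ctx.upper_prob)}


def _iv_boot_bca_qmle(ctx):
    return _iv_boot_bca(ctx, EstimatorMethod.QMLE, "boot_bca_qmle")


def _iv_boot_bca_mle(ctx):
    return _iv_boot_bca(ctx, EstimatorMethod.MLE, "boot_bca_mle")


def _iv_boot_np(ctx):
    two = bootstrap_ci(
        ctx.x,
        ctx.y,
        estimator=EstimatorMethod.NONPARAM,
        variant=NPVariant.LAPLACE,
        reps=ctx.boot_reps,
        level=ctx.level,
        rng=ctx.method_rng("boot_np_lls"),
    )
    return {"two_sided": two, "upper": _upper_from_two_sided(two, ctx.upper_prob)}


def _iv_hpd(ctx: ReplicateContext):
    post = ctx.posterior()
    return {
        "two_sided": hpd_interval(post, level=ctx.level, scale=Scale.PROBIT),
        "upper": posterior_upper_bound(post, ctx.upper_prob),
    }


DEFAULT_INTERVALS: Mapping[str, Callable[[ReplicateContext], dict]] = {
    "nct_mle": _iv_nct_mle,
    "nct_qmle": _iv_nct_qmle,
    "boot_bca_qmle": _iv_boot_bca_qmle,
    "hpd": _iv_hpd,
}


def run_scenario(
    spec: ScenarioSpec,
    plan: SimulationPlan,
    estimators: Optional[Mapping[str, Callable]] = None,
    interval_methods: Optional[Mapping[str, Callable]] = None,
    draws: int = 1000,
    boot_reps: int = 200,
    level: float = 0.90,
    upper_prob: float = 0.95,
    error_threshold: float = 0.01,
) -> ScenarioResult:
    """Run one scenario: B replicate datasets, all methods on each dataset.

    Datasets are pre-drawn from a stream keyed only by the scenario seed,
    and every method's randomness is keyed by (scenario seed, replicate,
    method name), so the result is reproducible and independent of which
    other methods run alongside.  Per-replicate method failures are
    recorded; a failure rate above ``error_threshold`` for any method
    raises.
    """
    if estimators is None:
        estimators = {k: DEFAULT_ESTIMATORS[k] for k in ("mle", "qmle", "bayes", "np_lls")}
    if interval_methods is None:
        interval_methods = dict(DEFAULT_INTERVALS)
    B = plan.B
    data_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xDA7A]))
    xs = data_rng.normal(spec.params.mu_x, spec.params.sigma_x, size=(B, spec.n_x))
    ys = data_rng.normal(spec.params.mu_y, spec.params.sigma_y, size=(B, spec.n_y))

    est_values: dict[str, list[float]] = {k: [] for k in estimators}
    iv_two: dict[str, list[IntervalEstimate]] = {k: [] for k in interval_methods}
    iv_up: dict[str, list[IntervalEstimate]] = {k: [] for k in interval_methods}
    errors: dict[str, int] = {k: 0 for k in (*estimators, *interval_methods)}

    for b in range(B):
        ctx = ReplicateContext(
            spec, b, xs[b], ys[b], draws, boot_reps, level, upper_prob
        )
        for name, fn in estimators.items():
            try:
                val = fn(ctx)
                est_values[name].append(getattr(val, "probit", val))
            except Exception:
                errors[name] += 1
        for name, fn in interval_methods.items():
            try:
                res = fn(ctx)
                if res.get("two_sided") is not None:
                    iv_two[name].append(res["two_sided"])
                if res.get("upper") is not None:
                    iv_up[name].append(res["upper"])
            except Exception:
                errors[name] += 1

    for name, count in errors.items():
        if count > error_threshold * B:
            raise RuntimeError(
                f"method {name!r} failed on {count}/{B} replicates "
                f"(threshold {error_threshold:.0%})"
            )

    true_z = true_risk(spec.params).probit
    point = {}
    quantiles = {}
    for name, vals in est_values.items():
        z = np.asarray(vals, dtype=float)
        point[name] = performance_measures(z, true_z)
        # order-statistic quantiles stay well defined with +-inf entries
        quantiles[name] = tuple(np.quantile(z, (0.025, 0.5, 0.975), method="lower"))
    two_sided = {
        name: coverage_and_length(ivs, spec.true_r) for name, ivs in iv_two.items() if ivs
    }
    upper = {
        name: coverage_and_length(ivs, spec.true_r) for name, ivs in iv_up.items() if ivs
    }
    return ScenarioResult(
        spec=spec,
        n_reps=B,
        point=point,
        quantiles=quantiles,
        two_sided=two_sided,
        upper=upper,
        error_counts=errors,
    )


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy DataFrame over scenarios (one row per scenario x method x kind)."""
    rows: list[dict] = []
    for res in results:
        rows.extend(res.to_rows())
    return pd.DataFrame(rows)
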