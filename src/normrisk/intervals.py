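"""Interval estimators for R: HPD, posterior percentile, bootstrap, noncentral t.

All constructions work on the probit scale (the working scale for small
risks) and report endpoints back on the probability scale.  Four families
are implemented:

* HPD credible intervals -- the narrowest window holding the requested
  posterior mass; *not* transformation invariant, so the construction
  scale is recorded;
* posterior percentile upper bounds -- empirical quantiles of the
  posterior draws of R;
* bootstrap percentile and BCa confidence intervals -- parametric or
  nonparametric resampling of the two samples, rank-based quantiles of the
  replicate estimates (transformation invariant);
* noncentral-t confidence intervals -- inversion of the noncentral t cdf
  at the observed statistic, with the summed variance approximated by a
  scaled chi-squared with Satterthwaite degrees of freedom.

For the percentile-type intervals the upper endpoint of a two-sided
100(1-alpha)% interval equals the one-sided upper bound at level
1 - alpha/2 (e.g. a 90% two-sided upper endpoint is the 95% upper bound).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .model import RiskValue, SampleStats, Scale, inverse_probit, summarize_sample
from .point import EstimatorMethod, NPVariant, estimate_np
from .bayes import PosteriorDraws

__all__ = [
    "Sidedness",
    "IntervalMethod",
    "BootScheme",
    "VarianceConvention",
    "IntervalEstimate",
    "NctWorkspace",
    "hpd_from_draws",
    "hpd_interval",
    "posterior_upper_bound",
    "bootstrap_ci",
    "bca_adjusted_levels",
    "satterthwaite_df",
    "nct_workspace",
    "noncentral_t_ci",
]


class Sidedness(str, enum.Enum):
    TWO_SIDED = "two_sided"
    UPPER_BOUND = "upper_bound"


class IntervalMethod(str, enum.Enum):
    HPD = "hpd"
    POSTERIOR_PERCENTILE = "posterior_percentile"
    BOOT_BCA = "boot_bca"
    BOOT_PERCENTILE = "boot_percentile"
    NONCENTRAL_T = "noncentral_t"


class BootScheme(str, enum.Enum):
    PARAMETRIC = "parametric"
    NONPARAMETRIC = "nonparametric"


class VarianceConvention(str, enum.Enum):
    """Which variance estimate a construction plugs in (divisor n-1 vs n)."""

    UNBIASED = "unbiased"
    MLE = "mle"


@dataclass(frozen=True)
class IntervalEstimate:
    """A confidence or credible interval for R on the probability scale."""

    lower: float
    upper: float
    level: float
    sidedness: Sidedness
    method: IntervalMethod
    scale_of_construction: Scale
    degenerate: bool = False
    fell_back_from_bca: bool = False
    n_failed: int = 0
    notes: str = ""
    replicates: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(
                f"invalid interval [{self.lower}, {self.upper}]: endpoints must "
                "satisfy 0 <= lower <= upper <= 1"
            )
        if self.degenerate != (self.lower == self.upper):
            raise ValueError("degenerate flag must mirror lower == upper")

    def contains(self, r: float) -> bool:
        """Endpoint-inclusive containment of a risk value."""
        return self.lower <= r <= self.upper

    @property
    def length_probit(self) -> float:
        """Interval length on the probit scale (may be inf at the boundaries)."""
        return float(stats.norm.ppf(self.upper) - stats.norm.ppf(self.lower))


@dataclass(frozen=True)
class NctWorkspace:
    """Intermediate quantities of the noncentral-t construction."""

    t_obs: float
    df: float
    lambda_hat: float
    ncp_lower: float
    ncp_upper: float

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not (0.0 < self.lambda_hat <= 1.0):
            raise ValueError("lambda_hat must lie in (0, 1]")


# --------------------------------------------------------------------------
# HPD and posterior percentile


def hpd_from_draws(values: Sequence[float], level: float) -> tuple[float, float]:
    """Shortest window holding a fraction ``level`` of the draws.

    Sorts the draws, sets w = floor(level * size) and returns the narrowest
    (draw[i], draw[i + w]) window.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if n * (1.0 - level) < 2.0:
        raise ValueError(
            f"too few draws ({n}) to resolve a {level:.0%} HPD interval"
        )
    w = int(math.floor(level * n))
    widths = values[w:] - values[: n - w]
    i = int(np.argmin(widths))
    return float(values[i]), float(values[i + w])


def hpd_interval(
    draws: PosteriorDraws,
    level: float = 0.90,
    scale: Scale = Scale.PROBIT,
) -> IntervalEstimate:
    """Highest posterior density credible interval for R.

    HPD intervals are not transformation invariant; the default follows the
    probit working scale and the construction scale is recorded on the
    result.
    """
    scale = Scale(scale)
    vals = draws.probit_r if scale is Scale.PROBIT else draws.r
    lo, hi = hpd_from_draws(vals, level)
    if scale is Scale.PROBIT:
        lo, hi = inverse_probit(lo), inverse_probit(hi)
    return IntervalEstimate(
        lower=lo,
        upper=hi,
        level=level,
        sidedness=Sidedness.TWO_SIDED,
        method=IntervalMethod.HPD,
        scale_of_construction=scale,
        degenerate=(lo == hi),
    )


def posterior_upper_bound(draws: PosteriorDraws, prob: float = 0.95) -> IntervalEstimate:
    """Upper credible bound: the ``prob`` empirical quantile of the R draws."""
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must lie in (0, 1)")
    if draws.size == 0:
        raise ValueError("no posterior draws")
    upper = float(np.quantile(draws.r, prob))
    return IntervalEstimate(
        lower=0.0,
        upper=upper,
        level=prob,
        sidedness=Sidedness.UPPER_BOUND,
        method=IntervalMethod.POSTERIOR_PERCENTILE,
        scale_of_construction=Scale.ORIGINAL,
        degenerate=(upper == 0.0),
    )


# --------------------------------------------------------------------------
# Bootstrap


def bca_adjusted_levels(
    z0: float, a: float, levels: Sequence[float]
) -> np.ndarray:
    """BCa-adjusted quantile levels.

    With bias correction z0 and acceleration a, the nominal level alpha is
    replaced by Phi(z0 + (z0 + z_alpha) / (1 - a (z0 + z_alpha))).  With
    z0 = a = 0 this reduces exactly to the nominal levels (the percentile
    method).
    """
    levels = np.asarray(levels, dtype=float)
    if z0 == 0.0 and a == 0.0:
        return levels.copy()  # exact percentile reduction
    z = stats.norm.ppf(levels)
    t = z0 + z
    return stats.norm.cdf(z0 + t / (1.0 - a * t))


def _order_statistic_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Empirical quantile as an order statistic (transformation invariant)."""
    n = sorted_vals.size
    idx = min(max(int(math.ceil(q * n)) - 1, 0), n - 1)
    return float(sorted_vals[idx])


def _probit_replicates(
    x: np.ndarray,
    y: np.ndarray,
    estimator: EstimatorMethod,
    variant: NPVariant,
    scheme: BootScheme,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap replicate estimates on the probit scale (nan = failed)."""
    n_x, n_y = x.size, y.size
    if scheme is BootScheme.PARAMETRIC:
        ddof = 0 if estimator is EstimatorMethod.MLE else 1
        xs = rng.normal(x.mean(), x.std(ddof=ddof), size=(reps, n_x))
        ys = rng.normal(y.mean(), y.std(ddof=ddof), size=(reps, n_y))
    else:
        xs = x[rng.integers(0, n_x, size=(reps, n_x))]
        ys = y[rng.integers(0, n_y, size=(reps, n_y))]
    if estimator in (EstimatorMethod.MLE, EstimatorMethod.QMLE):
        ddof = 0 if estimator is EstimatorMethod.MLE else 1
        vx = xs.var(axis=1, ddof=ddof)
        vy = ys.var(axis=1, ddof=ddof)
        total = vx + vy
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(total)
        z[total == 0.0] = np.nan
        return z
    out = np.empty(reps)
    for b in range(reps):
        out[b] = estimate_np(xs[b], ys[b], variant).probit
    return out


def _probit_estimate(
    x: np.ndarray, y: np.ndarray, estimator: EstimatorMethod, variant: NPVariant
) -> float:
    if estimator is EstimatorMethod.NONPARAM:
        return estimate_np(x, y, variant).probit
    sx = summarize_sample(x, "exposure sample")
    sy = summarize_sample(y, "effect sample")
    if estimator is EstimatorMethod.MLE:
        total = sx.var_mle + sy.var_mle
    else:
        total = sx.var_unbiased + sy.var_unbiased
    if total <= 0:
        raise ValueError("degenerate samples: zero total variance")
    return (sx.mean - sy.mean) / math.sqrt(total)


def _jackknife_acceleration(
    x: np.ndarray, y: np.ndarray, estimator: EstimatorMethod, variant: NPVariant
) -> float:
    """Grouped delete-one jackknife acceleration over all n_x + n_y points.

    a = sum(d^3) / (6 (sum(d^2))^{3/2}) with d_i = mean(jack) - jack_i on
    the probit scale.  Returns 0 when the jackknife values are degenerate
    or non-finite (e.g. the non-parametric estimator stuck at a boundary).
    """
    jack = []
    for i in range(x.size):
        jack.append(_probit_estimate(np.delete(x, i), y, estimator, variant))
    for j in range(y.size):
        jack.append(_probit_estimate(x, np.delete(y, j), estimator, variant))
    jack = np.asarray(jack)
    if not np.all(np.isfinite(jack)):
        return 0.0
    d = jack.mean() - jack
    denom = np.sum(d * d) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.sum(d**3) / (6.0 * denom))


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    estimator: EstimatorMethod = EstimatorMethod.QMLE,
    variant: NPVariant = NPVariant.LAPLACE,
    scheme: Optional[BootScheme] = None,
    method: IntervalMethod = IntervalMethod.BOOT_BCA,
    reps: int = 1000,
    level: float = 0.90,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    keep_replicates: bool = False,
) -> IntervalEstimate:
    """Bootstrap confidence interval (percentile or BCa) for R.

    The parametric scheme resamples each side from a normal with that
    side's sample mean and the estimator's own variance convention
    (divisor n for MLE, n-1 otherwise); the nonparametric scheme resamples
    with replacement within each sample.  The default scheme is parametric
    for MLE/QMLE and nonparametric for the non-parametric estimator.

    Replicates are handled on the probit scale; replicate estimates of
    exactly 0 or 1 are kept as signed infinities for the rank-based steps.
    An endpoint landing on an infinity is reported as 0 or 1 with a note.
    If the BCa bias correction is infinite (all replicates on one side of
    the point estimate) the interval falls back to the percentile method,
    recorded on the result.  Failed replicates are dropped and counted;
    more than 10% failures is an error.
    """
    estimator = EstimatorMethod(estimator)
    method = IntervalMethod(method)
    sidedness = Sidedness(sidedness)
    if method not in (IntervalMethod.BOOT_BCA, IntervalMethod.BOOT_PERCENTILE):
        raise ValueError(f"not a bootstrap method: {method}")
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if scheme is None:
        scheme = (
            BootScheme.NONPARAMETRIC
            if estimator is EstimatorMethod.NONPARAM
            else BootScheme.PARAMETRIC
        )
    scheme = BootScheme(scheme)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)

    theta_hat = _probit_estimate(x, y, estimator, variant)
    theta = _probit_replicates(x, y, estimator, variant, scheme, reps, rng)
    failed = np.isnan(theta)
    n_failed = int(failed.sum())
    if n_failed > 0.10 * reps:
        raise RuntimeError(
            f"{n_failed}/{reps} bootstrap replicates failed; the sampling "
            "model is too degenerate for a bootstrap interval"
        )
    theta = np.sort(theta[~failed])

    def finish(lo_z: float, hi_z: float, meth: IntervalMethod, fallback: bool) -> IntervalEstimate:
        notes = ""
        lo, hi = inverse_probit(lo_z), inverse_probit(hi_z)
        clamped = not math.isfinite(hi_z) or (
            sidedness is Sidedness.TWO_SIDED and not math.isfinite(lo_z)
        )
        if clamped:
            notes = "endpoint at a boundary replicate (probit infinity), clamped"
        if sidedness is Sidedness.UPPER_BOUND:
            lo = 0.0
        return IntervalEstimate(
            lower=min(lo, hi),
            upper=max(lo, hi),
            level=level,
            sidedness=sidedness,
            method=meth,
            scale_of_construction=Scale.PROBIT,
            degenerate=(min(lo, hi) == max(lo, hi)),
            fell_back_from_bca=fallback,
            n_failed=n_failed,
            notes=notes,
            replicates=theta if keep_replicates else None,
        )

    if theta[0] == theta[-1]:
        # zero-length interval: no variability among replicates
        z = theta[0]
        return finish(z if sidedness is Sidedness.TWO_SIDED else -np.inf, z, method, False)

    alpha = 1.0 - level
    if sidedness is Sidedness.TWO_SIDED:
        nominal = np.array([alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        nominal = np.array([level])

    if method is IntervalMethod.BOOT_BCA:
        frac_below = float(np.mean(theta < theta_hat))
        z0 = stats.norm.ppf(frac_below)
        if not math.isfinite(z0):
            method = IntervalMethod.BOOT_PERCENTILE
            fallback = True
            levels = nominal
        else:
            fallback = False
            a = _jackknife_acceleration(x, y, estimator, variant)
            levels = bca_adjusted_levels(z0, a, nominal)
    else:
        fallback = False
        levels = nominal

    qs = [_order_statistic_quantile(theta, q) for q in levels]
    if sidedness is Sidedness.TWO_SIDED:
        return finish(qs[0], qs[1], method, fallback)
    return finish(-np.inf, qs[0], method, fallback)


# --------------------------------------------------------------------------
# Noncentral t


def satterthwaite_df(stats_x: SampleStats, stats_y: SampleStats) -> float:
    """Satterthwaite degrees of freedom of the chi-squared approximation to
    s_x^2 + s_y^2:  f = (s_x^2 + s_y^2)^2 / (s_x^4/(n_x-1) + s_y^4/(n_y-1)).
    """
    vx, vy = stats_x.var_unbiased, stats_y.var_unbiased
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both sample variances are zero; df undefined")
    return float(
        (vx + vy) ** 2 / (vx**2 / (stats_x.n - 1) + vy**2 / (stats_y.n - 1))
    )


def _invert_nct_cdf(t_obs: float, df: float, q: float, xtol: float = 1e-10) -> float:
    """Solve F_nct(t_obs; df, ncp) = q for the noncentrality ncp.

    The cdf is strictly decreasing in ncp.  Uses an expanding bracket
    around t_obs (the root is within a few sampling standard deviations of
    it) followed by Brent's method; extreme noncentralities where the cdf
    underflows are never touched.
    """

    def fun(ncp: float) -> float:
        return stats.nct.cdf(t_obs, df, ncp) - q

    lo, hi = t_obs - 2.0, t_obs + 2.0
    step = 2.0
    while fun(lo) < 0.0:
        lo -= step
        step *= 2.0
        if step > 1e6:
            raise ArithmeticError(
                f"bracket failure inverting noncentral-t cdf: t_obs={t_obs}, "
                f"df={df}, q={q}, lower bracket {lo}"
            )
    step = 2.0
    while fun(hi) > 0.0:
        hi += step
        step *= 2.0
        if step > 1e6:
            raise ArithmeticError(
                f"bracket failure inverting noncentral-t cdf: t_obs={t_obs}, "
                f"df={df}, q={q}, upper bracket {hi}"
            )
    return float(optimize.brentq(fun, lo, hi, xtol=xtol))


def nct_workspace(
    stats_x: SampleStats,
    stats_y: SampleStats,
    level: float = 0.90,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    variance: VarianceConvention = VarianceConvention.UNBIASED,
) -> NctWorkspace:
    """Build the noncentral-t inversion workspace.

    ``variance`` selects which variance convention enters the observed
    statistic and the shrink factor lambda (matching the point estimator
    being intervalled); the chi-squared degrees of freedom always come from
    the unbiased variances, for which the chi-squared fact is exact.
    """
    variance = VarianceConvention(variance)
    if variance is VarianceConvention.MLE:
        vx, vy = stats_x.var_mle, stats_y.var_mle
    else:
        vx, vy = stats_x.var_unbiased, stats_y.var_unbiased
    se2 = vx / stats_x.n + vy / stats_y.n
    if se2 <= 0.0:
        raise ValueError("zero standard error; noncentral-t interval undefined")
    t_obs = (stats_x.mean - stats_y.mean) / math.sqrt(se2)
    df = satterthwaite_df(stats_x, stats_y)
    lam = se2 / (vx + vy)
    alpha = 1.0 - level
    if Sidedness(sidedness) is Sidedness.TWO_SIDED:
        q_lo, q_hi = 1.0 - alpha / 2.0, alpha / 2.0
    else:
        q_lo, q_hi = 1.0, alpha  # lower endpoint unused for an upper bound
    ncp_upper = _invert_nct_cdf(t_obs, df, q_hi)
    ncp_lower = -math.inf if q_lo == 1.0 else _invert_nct_cdf(t_obs, df, q_lo)
    return NctWorkspace(
        t_obs=t_obs, df=df, lambda_hat=lam, ncp_lower=ncp_lower, ncp_upper=ncp_upper
    )


def noncentral_t_ci(
    stats_x: SampleStats,
    stats_y: SampleStats,
    level: float = 0.90,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    variance: VarianceConvention = VarianceConvention.UNBIASED,
) -> IntervalEstimate:
    """Noncentral-t confidence interval for R.

    Finds the noncentralities whose noncentral-t cdf at the observed
    statistic equals 1 - alpha/2 and alpha/2 (monotone root-finding) and
    maps them through R = Phi(ncp * sqrt(lambda_hat)).
    """
    sidedness = Sidedness(sidedness)
    ws = nct_workspace(stats_x, stats_y, level, sidedness, variance)
    sqrt_lam = math.sqrt(ws.lambda_hat)
    upper = inverse_probit(ws.ncp_upper * sqrt_lam)
    if sidedness is Sidedness.TWO_SIDED:
        lower = inverse_probit(ws.ncp_lower * sqrt_lam)
    else:
        lower = 0.0
    return IntervalEstimate(
        lower=lower,
        upper=upper,
        level=level,
        sidedness=sidedness,
        method=IntervalMethod.NONCENTRAL_T,
        scale_of_construction=Scale.PROBIT,
        degenerate=(lower == upper),
    )
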