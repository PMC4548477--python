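"""Normal-normal risk model: true risk, probit transforms, sufficient statistics.

The model assumes independent normal distributions for log10 exposure
concentrations, ``X ~ N(mu_x, sigma_x)``, and log10 effect concentrations,
``Y ~ N(mu_y, sigma_y)``.  Note that the distributions are parameterized by
**standard deviation**, not variance.  The risk is

    R = P(X > Y) = Phi((mu_x - mu_y) / sqrt(sigma_x^2 + sigma_y^2))

where Phi is the standard normal cdf.  R depends on the parameters only
through the mean difference and the summed variance (location-scale
invariance), so any common shift of both means, or common rescaling of all
four parameters, leaves R unchanged.

All concentration values entering this module are assumed to be already
log10-transformed (see :mod:`normrisk.io` for the reader layer).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NormalNormalParams",
    "SampleStats",
    "RiskValue",
    "Scale",
    "JpcCurve",
    "true_risk",
    "probit_transform",
    "inverse_probit",
    "summarize_sample",
    "jpc_curve",
]


class Scale(str, enum.Enum):
    """Scale on which a summary or interval is constructed."""

    ORIGINAL = "original"
    PROBIT = "probit"


@dataclass(frozen=True)
class NormalNormalParams:
    """True parameters of the normal-normal model.

    Parameters
    ----------
    mu_x, mu_y : float
        Means of the log10 exposure and effect concentration distributions.
    sigma_x, sigma_y : float
        Standard deviations (not variances) of the two distributions; must
        be strictly positive.
    """

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        for name in ("mu_x", "mu_y", "sigma_x", "sigma_y"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError(
                "standard deviations must be strictly positive, got "
                f"sigma_x={self.sigma_x}, sigma_y={self.sigma_y}"
            )

    @property
    def diff_mean(self) -> float:
        """Mean of the difference X - Y."""
        return self.mu_x - self.mu_y

    @property
    def diff_sd(self) -> float:
        """Standard deviation of the difference X - Y."""
        return math.hypot(self.sigma_x, self.sigma_y)


@dataclass(frozen=True)
class SampleStats:
    """Sufficient statistics of one sample.

    Carries both variance conventions: ``var_unbiased`` uses divisor n - 1
    (the unbiased estimator s^2) and ``var_mle`` uses divisor n (the maximum
    likelihood estimator).
    """

    n: int
    mean: float
    var_unbiased: float
    var_mle: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 for variances to be defined, got n={self.n}")
        if self.var_unbiased < 0 or self.var_mle < 0:
            raise ValueError("variances must be nonnegative")

    @property
    def sd_unbiased(self) -> float:
        return math.sqrt(self.var_unbiased)

    @property
    def sd_mle(self) -> float:
        return math.sqrt(self.var_mle)


@dataclass(frozen=True)
class RiskValue:
    """A risk carried on both the probability and the probit scale.

    ``probit`` is the standard normal quantile of ``prob``; it is -inf at
    prob 0 and +inf at prob 1.  Infinities are propagated, never dropped:
    any aggregation over probit values containing them is reported as
    undefined rather than silently ignored.
    """

    prob: float
    probit: float

    @classmethod
    def from_prob(cls, prob: float) -> "RiskValue":
        return cls(prob=float(prob), probit=probit_transform(prob))

    @classmethod
    def from_probit(cls, probit: float) -> "RiskValue":
        return cls(prob=inverse_probit(probit), probit=float(probit))


def probit_transform(p: float) -> float:
    """Probit (inverse standard normal cdf) of a probability.

    By contract probit(0) = -inf and probit(1) = +inf.  Values outside
    [0, 1] raise a ``ValueError``.
    """
    p = float(p)
    if math.isnan(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    return float(stats.norm.ppf(p))


def inverse_probit(z: float) -> float:
    """Standard normal cdf; maps -inf -> 0 and +inf -> 1."""
    return float(stats.norm.cdf(z))


def true_risk(params: NormalNormalParams) -> RiskValue:
    """True risk R = P(X > Y) of a normal-normal model, on both scales."""
    z = params.diff_mean / params.diff_sd
    return RiskValue(prob=inverse_probit(z), probit=z)


def summarize_sample(values: Sequence[float], label: str = "sample") -> SampleStats:
    """Reduce a sample of log10 concentrations to its sufficient statistics.

    Raises an informative error (naming ``label``) for samples of size < 2
    or containing non-finite values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{label}: expected a 1-d sample, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(
            f"{label}: at least 2 observations are required to estimate a "
            f"variance, got n={arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{label}: sample contains non-finite values")
    n = int(arr.size)
    mean = float(arr.mean())
    ss = float(np.sum((arr - mean) ** 2))
    return SampleStats(n=n, mean=mean, var_unbiased=ss / (n - 1), var_mle=ss / n)


@dataclass(frozen=True)
class JpcCurve:
    """A joint probability curve and the numeric area under it.

    The JPC plots the exceedance function of the exposure distribution
    (``exceedance`` = 1 - F_X) against the cdf of the effect distribution
    (``ssd_cdf`` = F_Y); the area under this curve equals the risk R.
    """

    ssd_cdf: np.ndarray
    exceedance: np.ndarray
    area: float


def jpc_curve(params: NormalNormalParams, grid_size: int = 10_000) -> JpcCurve:
    """Joint probability curve of a normal-normal model.

    The curve is sampled at a uniform grid of the effect-distribution cdf;
    the area is obtained by Simpson integration along the curve and serves
    as an independent quadrature oracle for :func:`true_risk`.
    """
    if grid_size < 10:
        raise ValueError(f"grid_size must be >= 10, got {grid_size}")
    from scipy.integrate import simpson

    # Parametrize the curve by concentration over a range covering both
    # distributions; integrating the exceedance against the SSD density is
    # the area under the curve in (F_Y, 1 - F_X) coordinates and avoids the
    # endpoint-singular slope of cdf-space parametrizations.
    lo = min(params.mu_x - 10 * params.sigma_x, params.mu_y - 10 * params.sigma_y)
    hi = max(params.mu_x + 10 * params.sigma_x, params.mu_y + 10 * params.sigma_y)
    y = np.linspace(lo, hi, int(grid_size))
    u = stats.norm.cdf(y, loc=params.mu_y, scale=params.sigma_y)
    exceed = stats.norm.sf(y, loc=params.mu_x, scale=params.sigma_x)
    dens = stats.norm.pdf(y, loc=params.mu_y, scale=params.sigma_y)
    area = float(simpson(exceed * dens, x=y))
    return JpcCurve(ssd_cdf=u, exceedance=exceed, area=area)
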