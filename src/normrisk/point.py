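"""Point estimators of the risk R = P(X > Y).

Four estimators are provided:

* MLE -- plug-in of sample means and divisor-n (maximum likelihood)
  variances into the normal-normal risk formula;
* QMLE -- the same with unbiased (divisor n - 1) variances;
* the Bayesian posterior summaries (in :mod:`normrisk.bayes`);
* a non-parametric estimator U / (n_x n_y), where U is the Mann-Whitney
  statistic, with the zero-correction variants used when no exposure value
  exceeds any effect value: Laplace's Law of Succession (U+1)/(n_x n_y + 2),
  the half-range substitute 1/(2 n_x n_y) and the plus-one substitute
  1/(n_x n_y + 1).

The non-parametric estimator equals the area under the empirical ROC curve
and is invariant under strictly monotone transformations of both samples.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .model import RiskValue, SampleStats, summarize_sample

__all__ = [
    "EstimatorMethod",
    "NPVariant",
    "BayesSummary",
    "RiskEstimate",
    "estimate_mle",
    "estimate_qmle",
    "mann_whitney_u",
    "estimate_np",
]


class EstimatorMethod(str, enum.Enum):
    MLE = "mle"
    QMLE = "qmle"
    BAYES = "bayes"
    NONPARAM = "nonparam"


class NPVariant(str, enum.Enum):
    """Zero-correction variants of the non-parametric estimator."""

    RAW = "raw"
    LAPLACE = "laplace"
    HALF_RANGE = "half_range"
    PLUS_ONE = "plus_one"


class BayesSummary(str, enum.Enum):
    MEAN = "mean"
    MEDIAN = "median"
    MODE = "mode"


@dataclass(frozen=True)
class RiskEstimate:
    """A point estimate of R tagged with its method and sample sizes."""

    value: RiskValue
    method: EstimatorMethod
    n_x: int
    n_y: int
    variant: Optional[enum.Enum] = None

    def __post_init__(self) -> None:
        needs_variant = self.method in (EstimatorMethod.NONPARAM, EstimatorMethod.BAYES)
        if needs_variant and self.variant is None:
            raise ValueError(f"method {self.method} requires a variant tag")
        if not needs_variant and self.variant is not None:
            raise ValueError(f"method {self.method} does not take a variant tag")

    @property
    def prob(self) -> float:
        return self.value.prob

    @property
    def probit(self) -> float:
        return self.value.probit


def _plugin_probit(stats_x: SampleStats, stats_y: SampleStats, var_x: float, var_y: float) -> float:
    total = var_x + var_y
    if total <= 0.0:
        raise ValueError(
            "degenerate samples: both variance estimates are zero, the "
            "plug-in risk estimator is undefined"
        )
    return (stats_x.mean - stats_y.mean) / math.sqrt(total)


def estimate_mle(stats_x: SampleStats, stats_y: SampleStats) -> RiskEstimate:
    """Maximum likelihood estimator of R (divisor-n variances)."""
    z = _plugin_probit(stats_x, stats_y, stats_x.var_mle, stats_y.var_mle)
    return RiskEstimate(
        value=RiskValue.from_probit(z),
        method=EstimatorMethod.MLE,
        n_x=stats_x.n,
        n_y=stats_y.n,
    )


def estimate_qmle(stats_x: SampleStats, stats_y: SampleStats) -> RiskEstimate:
    """Quasi maximum likelihood estimator of R (unbiased variances)."""
    z = _plugin_probit(stats_x, stats_y, stats_x.var_unbiased, stats_y.var_unbiased)
    return RiskEstimate(
        value=RiskValue.from_probit(z),
        method=EstimatorMethod.QMLE,
        n_x=stats_x.n,
        n_y=stats_y.n,
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U statistic: number of (x_i, y_j) pairs with x_i > y_j.

    Ties count with weight 1/2, so U may be half-integral;
    0 <= U <= n_x * n_y.  Computed from midranks of the pooled sample in
    O((n_x + n_y) log(n_x + n_y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain non-finite values")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    rank_sum_x = float(ranks[: x.size].sum())
    u = rank_sum_x - x.size * (x.size + 1) / 2.0
    # guard against tiny float error at the boundaries
    return float(min(max(u, 0.0), float(x.size) * float(y.size)))


def estimate_np(
    x: Sequence[float],
    y: Sequence[float],
    variant: NPVariant = NPVariant.LAPLACE,
) -> RiskEstimate:
    """Non-parametric estimator of R with zero-correction variants.

    RAW is U / (n_x n_y) and may be exactly 0 or 1, in which case its
    probit is -inf or +inf.  LAPLACE applies Laplace's Law of Succession
    (U + 1) / (n_x n_y + 2) everywhere, keeping the estimate strictly
    inside (0, 1) (Cromwell's rule).  HALF_RANGE and PLUS_ONE equal RAW
    except at the boundaries, where 0 is replaced by 1/(2 n_x n_y)
    resp. 1/(n_x n_y + 1), and symmetrically 1 by one minus that bound.
    """
    variant = NPVariant(variant)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = mann_whitney_u(x, y)
    n_pairs = x.size * y.size
    raw = u / n_pairs
    if variant is NPVariant.RAW:
        value = raw
    elif variant is NPVariant.LAPLACE:
        value = (u + 1.0) / (n_pairs + 2.0)
    else:
        bound = (
            1.0 / (2.0 * n_pairs) if variant is NPVariant.HALF_RANGE else 1.0 / (n_pairs + 1.0)
        )
        if raw == 0.0:
            value = bound
        elif raw == 1.0:
            value = 1.0 - bound
        else:
            value = raw
    return RiskEstimate(
        value=RiskValue.from_prob(value),
        method=EstimatorMethod.NONPARAM,
        n_x=int(x.size),
        n_y=int(y.size),
        variant=variant,
    )


def estimate_from_samples(
    x: Sequence[float],
    y: Sequence[float],
    method: EstimatorMethod,
    variant: NPVariant = NPVariant.LAPLACE,
) -> RiskEstimate:
    """Convenience dispatcher from raw samples (MLE/QMLE/NP only)."""
    method = EstimatorMethod(method)
    if method is EstimatorMethod.NONPARAM:
        return estimate_np(x, y, variant)
    sx = summarize_sample(x, "exposure sample")
    sy = summarize_sample(y, "effect sample")
    if method is EstimatorMethod.MLE:
        return estimate_mle(sx, sy)
    if method is EstimatorMethod.QMLE:
        return estimate_qmle(sx, sy)
    raise ValueError(
        "estimate_from_samples handles MLE/QMLE/NONPARAM; use "
        "normrisk.bayes for the Bayesian estimator"
    )
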