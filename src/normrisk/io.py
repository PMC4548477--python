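"""Data ingestion, fixture generation and the case-study runner.

Concentration files are one numeric value per line (a single-column CSV
with an optional header is accepted).  Values are log10 concentrations by
default; raw concentrations can be log10-transformed on read.  The
case-study runner assembles the full report of point estimates, 90%
two-sided intervals and 95% upper bounds for every estimator, computed on
the probit scale and transformed back to probabilities.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import SampleStats, Scale, summarize_sample, true_risk
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
    BootScheme,
    IntervalEstimate,
    IntervalMethod,
    Sidedness,
    VarianceConvention,
    bootstrap_ci,
    hpd_interval,
    noncentral_t_ci,
    posterior_upper_bound,
)
from .simulate import ScenarioSpec

__all__ = [
    "Dataset",
    "CaseStudyConfig",
    "ReportRow",
    "CaseStudyReport",
    "read_concentrations",
    "generate_fixture",
    "average_per_species",
    "normality_diagnostics",
    "run_case_study",
]


@dataclass(frozen=True)
class Dataset:
    """A sample of log10 concentrations with provenance metadata."""

    values: np.ndarray
    label: str
    already_log: bool = True
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.values.size < 1:
            raise ValueError(f"{self.label}: empty dataset")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.label}: non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def stats(self) -> SampleStats:
        return summarize_sample(self.values, self.label)


def read_concentrations(
    path: str | Path,
    already_log: bool = True,
    label: Optional[str] = None,
) -> Dataset:
    """Read a one-column concentration file.

    One numeric per line; a single non-numeric first line is treated as a
    header.  With ``already_log=False`` values are log10-transformed and
    non-positive raw concentrations are rejected.
    """
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().rstrip(",")
            if not text:
                continue
            try:
                v = float(text)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise ValueError(
                    f"{path}: could not parse line {lineno}: {line.strip()!r}"
                ) from None
            values.append(v)
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{path}: no numeric values found")
    if not already_log:
        if np.any(arr <= 0.0):
            bad = int(np.argmax(arr <= 0.0))
            raise ValueError(
                f"{path}: non-positive concentration {arr[bad]} cannot be "
                "log-transformed (value index {bad})"
            )
        arr = np.log10(arr)
    return Dataset(
        values=arr,
        label=label or path.stem,
        already_log=True,
        source_path=str(path),
    )


def average_per_species(
    values: Sequence[float], species: Sequence[str]
) -> np.ndarray:
    """Arithmetic mean of log10 endpoints per species (optional pre-step).

    Collapses multiple toxicity endpoints per species to one value each,
    averaging on the log scale; species order of first appearance is kept.
    Off by default in the pipeline: input files are assumed to be already
    species-aggregated.
    """
    values = np.asarray(values, dtype=float)
    seen: dict[str, list[float]] = {}
    for v, s in zip(values, species, strict=True):
        seen.setdefault(s, []).append(v)
    return np.array([float(np.mean(v)) for v in seen.values()])


def normality_diagnostics(dataset: Dataset) -> dict:
    """Optional omnibus normality screens (diagnostic only).

    Returns p-values of the Shapiro-Wilk and D'Agostino-Pearson tests.
    Low power at small n and excess power at large n mean these should
    inform, not gate, the normal-normal analysis.
    """
    x = dataset.values
    out = {"n": int(x.size)}
    if x.size >= 3:
        out["shapiro_p"] = float(sps.shapiro(x).pvalue)
    if x.size >= 20:
        out["dagostino_p"] = float(sps.normaltest(x).pvalue)
    return out


def generate_fixture(
    spec: ScenarioSpec, out_dir: str | Path, seed: int
) -> dict:
    """Write an exposure/effect fixture pair plus a JSON manifest.

    Draws one dataset from the scenario's true model.  Regeneration with
    the same seed is byte-identical (fixed float formatting).  Returns the
    manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    x = rng.normal(spec.params.mu_x, spec.params.sigma_x, size=spec.n_x)
    y = rng.normal(spec.params.mu_y, spec.params.sigma_y, size=spec.n_y)
    for name, arr in (("exposure.csv", x), ("effect.csv", y)):
        with open(out_dir / name, "w") as fh:
            for v in arr:
                fh.write(f"{v:.17g}\n")
    manifest = {
        "n_x": spec.n_x,
        "n_y": spec.n_y,
        "sigma_ratio": spec.sigma_ratio,
        "true_r": true_risk(spec.params).prob,
        "params": dataclasses.asdict(spec.params),
        "seed": seed,
        "files": ["exposure.csv", "effect.csv"],
        "already_log": True,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------------------------------
# Case study


@dataclass(frozen=True)
class CaseStudyConfig:
    draws: int = 10_000
    boot_reps: int = 1000
    seed: int = 0
    level: float = 0.90
    upper_prob: float = 0.95


@dataclass(frozen=True)
class ReportRow:
    label: str
    estimate: float
    ci_lower: float
    ci_upper: float
    upper_bound: float
    method: str
    degenerate: bool = False
    notes: str = ""


@dataclass(frozen=True)
class CaseStudyReport:
    rows: tuple
    n_x: int
    n_y: int
    sd_ratio: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_x": self.n_x,
            "n_y": self.n_y,
            "sd_ratio": self.sd_ratio,
            "settings": dict(self.settings),
            "rows": [dataclasses.asdict(r) for r in self.rows],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CaseStudyReport":
        d = json.loads(text)
        return cls(
            rows=tuple(ReportRow(**r) for r in d["rows"]),
            n_x=d["n_x"],
            n_y=d["n_y"],
            sd_ratio=d["sd_ratio"],
            settings=d["settings"],
        )

    def format_table(self, precision: int = 4) -> str:
        """Plain-text report table, probabilities rounded to ``precision``."""
        p = precision
        lines = [
            f"{'Estimator':<22} {'R_hat':>8} {'90% two-sided CI':>19} {'95% upper CB':>13}"
        ]
        for r in self.rows:
            ci = f"{r.ci_lower:.{p}f}-{r.ci_upper:.{p}f}"
            lines.append(
                f"{r.label:<22} {r.estimate:>8.{p}f} {ci:>19} {r.upper_bound:>13.{p}f}"
            )
        return "\n".join(lines)


def run_case_study(
    exposure: Dataset, effect: Dataset, config: CaseStudyConfig = CaseStudyConfig()
) -> CaseStudyReport:
    """Full case-study analysis: every estimator with its interval(s).

    Rows (in order): MLE with its noncentral-t interval, QMLE with
    noncentral-t and parametric-BCa-bootstrap intervals, the Bayesian
    posterior median with probit-scale HPD interval and 95% posterior
    percentile upper bound, and the empirical (non-parametric, Laplace
    Law of Succession) estimate with a nonparametric bootstrap interval.
    All estimates and intervals are computed on the probit scale and
    reported back on the probability scale.
    """
    sx = exposure.stats()
    sy = effect.stats()
    cfg = config

    rows = []

    def add(label, est, two: IntervalEstimate, up: IntervalEstimate, method, notes=""):
        rows.append(
            ReportRow(
                label=label,
                estimate=est,
                ci_lower=two.lower,
                ci_upper=two.upper,
                upper_bound=up.upper,
                method=method,
                degenerate=two.degenerate,
                notes=notes,
            )
        )

    # MLE row: noncentral t with the MLE's own variance convention
    mle = estimate_mle(sx, sy)
    two = noncentral_t_ci(sx, sy, cfg.level, variance=VarianceConvention.MLE)
    up = noncentral_t_ci(
        sx, sy, cfg.upper_prob, Sidedness.UPPER_BOUND, VarianceConvention.MLE
    )
    add("MLE", mle.prob, two, up, "noncentral t")

    # QMLE rows: noncentral t and parametric BCa bootstrap
    qmle = estimate_qmle(sx, sy)
    two = noncentral_t_ci(sx, sy, cfg.level, variance=VarianceConvention.UNBIASED)
    up = noncentral_t_ci(
        sx, sy, cfg.upper_prob, Sidedness.UPPER_BOUND, VarianceConvention.UNBIASED
    )
    add("QMLE (noncentral t)", qmle.prob, two, up, "noncentral t")

    two = bootstrap_ci(
        exposure.values,
        effect.values,
        estimator=EstimatorMethod.QMLE,
        scheme=BootScheme.PARAMETRIC,
        method=IntervalMethod.BOOT_BCA,
        reps=cfg.boot_reps,
        level=cfg.level,
        seed=cfg.seed,
    )
    up_boot = IntervalEstimate(
        lower=0.0,
        upper=two.upper,
        level=cfg.upper_prob,
        sidedness=Sidedness.UPPER_BOUND,
        method=two.method,
        scale_of_construction=two.scale_of_construction,
        degenerate=(two.upper == 0.0),
    )
    add(
        "QMLE (bootstrap)",
        qmle.prob,
        two,
        up_boot,
        "parametric BCa bootstrap",
        notes="fell back to percentile" if two.fell_back_from_bca else "",
    )

    # Bayes row: posterior median, probit-scale HPD, percentile upper bound
    post = sample_posterior(sx, sy, draws=cfg.draws, seed=cfg.seed)
    bayes = posterior_point(post, BayesSummary.MEDIAN, Scale.PROBIT)
    two = hpd_interval(post, cfg.level, Scale.PROBIT)
    up = posterior_upper_bound(post, cfg.upper_prob)
    add("Bayes", bayes.prob, two, up, "posterior median, HPD / percentile")

    # Empirical row: Laplace Law of Succession, nonparametric bootstrap
    emp = estimate_np(exposure.values, effect.values, NPVariant.LAPLACE)
    two = bootstrap_ci(
        exposure.values,
        effect.values,
        estimator=EstimatorMethod.NONPARAM,
        variant=NPVariant.LAPLACE,
        scheme=BootScheme.NONPARAMETRIC,
        reps=cfg.boot_reps,
        level=cfg.level,
        seed=cfg.seed,
    )
    up_boot = IntervalEstimate(
        lower=0.0,
        upper=two.upper,
        level=cfg.upper_prob,
        sidedness=Sidedness.UPPER_BOUND,
        method=two.method,
        scale_of_construction=two.scale_of_construction,
        degenerate=(two.upper == 0.0),
    )
    add(
        "Empirical",
        emp.prob,
        two,
        up_boot,
        "Laplace Law of Succession, nonparametric bootstrap",
        notes="zero-length interval" if two.degenerate else "",
    )

    sd_ratio = math.sqrt(sy.var_unbiased / sx.var_unbiased)
    return CaseStudyReport(
        rows=tuple(rows),
        n_x=sx.n,
        n_y=sy.n,
        sd_ratio=sd_ratio,
        settings=dataclasses.asdict(cfg),
    )
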