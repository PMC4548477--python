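# Methods

This note documents the statistical models and algorithms implemented in
`normrisk`, the numerical choices behind them, what the synthetic data
emulate, and the package's known limitations.

## Model

Log10 exposure concentrations X and log10 effect concentrations Y are
independent normals, X ~ N(μx, σx), Y ~ N(μy, σy) — parameterized by
**standard deviation**, not variance, throughout the package.  Then
X − Y ~ N(μx − μy, √(σx² + σy²)) and the risk is

    R = P(X > Y) = Φ((μx − μy)/√(σx² + σy²)).

R is invariant under a common shift of both means and under a common
rescaling of all four parameters, so simulation scenarios anchor μy = 0,
σx = 1 without loss of generality.  R also equals the area under the joint
probability curve (JPC: ECD exceedance vs SSD cdf); `jpc_curve` computes
that area by Simpson quadrature of the exceedance against the SSD density
over a ±10 sd concentration range, parametrizing by concentration rather
than by cdf because the cdf-space curve has endpoint-singular slope
whenever σx > σy.  The area agrees with the closed form to machine
precision at the default 10⁴-point grid and serves as an independent
oracle for `true_risk` in the tests.

### Probit scale

All small-risk work happens on the probit scale z = Φ⁻¹(R).  The contract
is probit(0) = −∞ and probit(1) = +∞; infinities are *propagated*, never
dropped.  Any replicate aggregation that encounters a non-finite probit
(the raw non-parametric estimator at a boundary) is reported as undefined
with a count, rather than being computed on a silently truncated sample.

## Point estimators

* **MLE**: Φ((x̄ − ȳ)/√(σ̂x² + σ̂y²)) with divisor-n variances.
* **QMLE**: same plug-in with unbiased (divisor n−1) variances.  Since
  s² ≥ σ̂², the QMLE always shrinks the probit estimate toward 0
  (R toward 0.5) relative to the MLE — a tested invariant.
* **Non-parametric**: R̂ = U/(n_x n_y), U the Mann–Whitney count of pairs
  with x > y; ties count ½, so U may be half-integral.  U is computed from
  midranks of the pooled sample in O(n log n) and checked against a
  pairwise double loop.  Zero-correction variants: Laplace's Law of
  Succession (U+1)/(n_x n_y + 2) applied everywhere — with k taken as U
  including tie half-weights, so the estimator remains continuous in the
  data — and the substitutes 1/(2 n_x n_y) and 1/(n_x n_y + 1), applied
  only at the boundaries and symmetrically at both ends (at R̂ = 1 the
  substitute is one minus the bound), preserving swap antisymmetry
  R̂(x,y) + R̂(y,x) = 1.
* **Bayesian**: below.

Samples of size 1 are rejected for MLE/QMLE (no variance estimate) but
accepted by the non-parametric estimator.

## Bayesian inference

With the non-informative priors p(μ, σ²) ∝ 1/σ² per sample, the posterior
factorizes:

    σx² ~ Inv-Gamma((n_x−1)/2, (n_x−1)s_x²/2),   μx | σx² ~ N(x̄, σx/√n_x),

and likewise for y.  `sample_posterior` uses the Method of Composition
(variances from their marginals, then means from their conditionals, then
R from the risk formula), vectorized over draws; a fixed seed gives
bit-identical output.  The default posterior sample size is 10,000; 1,000
is adequate for simulation work and is the simulation engine's default.

The marginal posterior density of R is also available without Monte Carlo
error: conditionally on (σx², σy²), probit(R) is normal with mean
(x̄ − ȳ)/√(σx² + σy²) and sd √((σx²/n_x + σy²/n_y)/(σx² + σy²)).
`marginal_pdf` integrates this conditional density over the two
inverse-gamma posteriors by mapping each variance to its posterior cdf
scale and applying a tensor-product Gauss–Legendre rule (64×64 nodes by
default) on the unit square.  The quadrature-implied cdf and 10⁵
composition draws agree with a one-sample KS statistic below the 1%
critical value (tested), the density integrates to 1 within 10⁻³, and its
peak matches the MLE at large n.

Point summaries: posterior **median** is the default (scale-equivariant, so
identical whether computed on the probability or probit scale — tested);
mean and mode are scale-dependent and exposed with an explicit scale
argument.  The mode is extracted from a Gaussian KDE with Silverman
bandwidth on a 2048-point grid; on the original scale with small risks the
posterior is extremely right-skewed and the KDE mode collapses toward
zero while the mean is inflated (mean > median > mode), which is why the
median on the probit scale is the recommended estimator.

## Interval estimators

All two-sided intervals default to 90%, upper bounds to 95%.

* **HPD**: sort the draws, w = ⌊level·size⌋, take the narrowest window
  (draw[i], draw[i+w]).  HPD intervals are not transformation invariant;
  the default construction scale is probit (matching the working scale)
  and the scale used is recorded on the result.
* **Posterior percentile**: the empirical quantile of the R draws.
* **Bootstrap** (percentile and BCa): the parametric scheme resamples each
  side from a normal with the sample mean and the estimator's own variance
  convention (divisor-n sd for the MLE, divisor-(n−1) otherwise); the
  nonparametric scheme resamples within each sample with replacement, and
  is the default for the non-parametric estimator, which has no fitted
  sampling model.  Replicates are ranked on the probit scale with
  order-statistic quantiles, making percentile (and, given the ranks, BCa)
  endpoints exactly invariant under the probit transform.  Boundary
  replicates are kept as ±∞ for ranking; an endpoint landing on ±∞ is
  reported as 0 or 1 with a note.  BCa: z₀ = Φ⁻¹(fraction of replicates
  strictly below the point estimate); acceleration a from the grouped
  delete-one jackknife over all n_x + n_y observations,
  a = Σd³/(6(Σd²)^{3/2}), d_i = mean(jack) − jack_i on the probit scale
  (set to 0 if any jackknife value is non-finite).  If z₀ is infinite (all
  replicates on one side) the interval falls back to the percentile
  method, recorded on the result; if all replicates coincide the interval
  is returned degenerate (zero length) — exactly what happens to the
  non-parametric estimator on non-overlapping samples.  Replicates that
  fail (zero resample variance) are dropped and counted; above 10% the
  call errors.
* **Noncentral t**: t_obs = (x̄ − ȳ)/√(v̂x/n_x + v̂y/n_y) follows
  approximately a noncentral t with Satterthwaite degrees of freedom
  f = (s_x² + s_y²)²/(s_x⁴/(n_x−1) + s_y⁴/(n_y−1)) and noncentrality
  δ/√λ, λ = (v̂x/n_x + v̂y/n_y)/(v̂x + v̂y).  The confidence limits solve
  F_nct(t_obs; f, ncp) = 1−α/2 and α/2 by bracketed Brent root-finding
  (tolerance 10⁻¹⁰; the bracket expands outward from t_obs, where the
  root must lie, avoiding the extreme noncentralities at which scipy's
  cdf underflows to NaN) and map to R = Φ(ncp·√λ).  The variance
  convention v̂ entering t_obs and λ is selectable so the interval can
  match either the MLE or the QMLE plug-in; f always uses the unbiased
  variances, for which the chi-squared distributional fact is exact.

For percentile-type constructions the upper endpoint of the 90% two-sided
interval doubles as the 95% one-sided upper bound; for HPD the two can
differ in either direction because the tail masses of an HPD window are
unequal in general (tested).

## Simulation engine

Scenario grid defaults: n_x ∈ {5, 100}, n_y ∈ {2, 5, 12, 20, 100},
σy/σx ∈ {1, 1/5, 5}, and a risk grid
{1e−14, 1e−10, 1e−7, 1e−5, 1e−3, 0.01, 0.05, 0.1, 0.25, 0.5} spanning
the very small risks relevant to this application up to the
no-separation case (the grid is configurable; risks above 0.5 trigger a
warning since R and 1−R are symmetric).  μx is solved from the target
risk; per-scenario seeds derive deterministically from a master seed.

Within a scenario, every estimator and interval method is evaluated on the
same pre-drawn dataset per replicate, and each method's internal
randomness is keyed by (scenario seed, replicate index, method name), so
results are reproducible and independent of which other methods run
alongside — adding a method can never change another method's numbers
(tested).  Replicate counts come from the pilot formula
B = (z·sd/δ)², rounded up to the next multiple of 100 by default
(4477.58 → 4,500 for the published pilot values; a multiple-of-500 policy
and plain ceiling are also available).

Performance measures on the probit scale: mean, bias, empirical SD with
the number of replicates as divisor, RMSE = √(bias² + SD²) (identity
tested to 10⁻¹⁰).  Non-finite probit estimates make a summary undefined
rather than silently shrinking the denominator; accordingly the default
estimator set tracks the Laplace variant of the non-parametric estimator
for performance measures, with the raw variant available for sampling
distribution quantile fans.  Interval summaries: endpoint-inclusive
coverage, median probit length, and the length (or upper-bound minus
truth) relative to |probit(R)| — undefined at R = 0.5 and reported as NaN
there, with the absolute value always available.  Degenerate and
infinite-length intervals are counted, not discarded.  Results export as
a tidy DataFrame/CSV, one row per scenario × method × summary kind.

The scaled-down study exercised by the tests uses the scenario closest to
the case study (n_x = 100, n_y = 12, σy = 5σx) at R ∈ {0.01, 0.1} with
B = 500 replicates, 1,000 posterior draws and 200 bootstrap replicates —
sizes chosen so the full comparison (point RMSE ordering Bayes ≤ QMLE ≤
MLE, near-nominal HPD coverage, liberal bootstrap coverage, and the
non-parametric estimator pinned at its Laplace bound probit(1/1202) for
R = 0.01) is sharp at binomial-error tolerances while the suite stays
fast.

## Synthetic data

The simulation generator draws i.i.d. normal samples — by construction it
matches the model, so simulation results quantify estimator behaviour
*under a correctly specified model* and say nothing about robustness to
non-normal tails, dependence between exposure and effect, or measurement
error structure in real monitoring data.

`datasets.synthetic_case_study` is a deterministic, moment-matched
synthetic stand-in for the motivating nano-Ag dataset: 1,000 exposure and
12 effect log10 concentrations built from standardized normal scores with
exactly the published summary configuration (sd ratio 5.6; mean
separation pinned by the published plug-in risk of 0.0090; exposure
anchored at mean −2.0, sd 0.2 — location and scale do not affect any
estimate).  Every parametric estimator and interval here depends on the
data only through (n, mean, sd), so those analyses coincide with analyses
of the original data; the samples do not overlap, so the non-parametric
results (U = 0) coincide as well.  What is *not* pinned by moments: the
BCa jackknife acceleration uses delete-one (third-moment) information, so
the bootstrap-BCa endpoints on the synthetic data are close to, but not
identical with, what the original data would give.

## Numerical choices and degenerate inputs

* Quantiles of bootstrap replicates and of simulation sampling
  distributions use order statistics (no interpolation): transformation
  invariant and well defined with ±∞ entries.
* `bca_adjusted_levels` returns the nominal levels exactly when
  z₀ = a = 0 rather than round-tripping through Φ/Φ⁻¹.
* Constant samples: MLE/QMLE and the noncentral-t interval raise on zero
  total variance; the Bayesian posterior is improper for n < 2 or zero
  sample variance and raises; the non-parametric estimator is unaffected.
* Fixture files are written with 17-significant-digit formatting, so
  regeneration is byte-identical and read-back reproduces estimates
  bit-for-bit.
* The case-study report rounds to 4 decimal places on the probability
  scale; underlying values are exact in the returned objects.

## Limitations

* Only the normal–normal model: no log-logistic or other SSD forms, no
  dependence between X and Y, no informative or probability-matching
  priors (the non-informative prior pulls R toward 0.5 in tiny samples —
  visible in the prior-dominated-limit test).
* The non-parametric estimator cannot see below ~1/(n_x n_y); its
  performance measures near that bound are dominated by the bound itself.
* Normality screening (`normality_diagnostics`) is a convenience
  diagnostic (Shapiro–Wilk, D'Agostino–Pearson), not a model-selection
  procedure.
* No plotting; simulation output is tidy CSV/JSON intended for downstream
  graphics.
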