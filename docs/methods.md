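# Methods

This note records the statistical models implemented in `mchbench`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would want
written down.

## Survey extraction

**Weighted coverage.** The estimator is the weighted ratio mean
p̂ = Σwᵢyᵢ / Σwᵢ over denominator records inside the indicator's age
window (records outside the window are dropped before anything else is
computed, matching standard survey practice for immunization and
most-recent-birth indicators). The variance treats clusters as
with-replacement primary sampling units: with cluster residual totals
z_c = Σ_{k∈c} w_k(y_k − p̂), var(p̂) = m/(m−1)·Σ_c z_c² / (Σw)². Because
Σ_c z_c = 0 analytically for the ratio estimator, the centred and
uncentred forms agree; the tests exploit this by checking against an
independently coded centred implementation. A single-cluster input
falls back to the weighted SRS variance; an empty denominator returns a
flagged missing estimate rather than raising, so one empty survey cell
cannot abort a pipeline run. Estimates are invariant to rescaling all
weights by a positive constant.

**Transforms.** Proportions are modelled on the logit scale with
delta-method variance var/(p(1−p))²; positive quantities (e.g. years of
maternal education) on the log scale with variance var/x². Before the
logit, estimates are clamped to [1/(4n_eff), 1 − 1/(4n_eff)]
(fallback [0.001, 0.999] when n_eff is unknown): a quarter-count keeps
the transform finite without materially moving any interior estimate.
When a source reports a point estimate with no usable SE, a binomial SE
from n_eff is imputed; with neither, the observation is rejected.

**Direct ⁵q₀.** Age segments default to {0, 1–5, 6–11, 12–23, 24–35,
36–47, 48–59} months, the synthetic-cohort convention; they are
configurable. Within a calendar period, each segment's weighted deaths
D_a and child-month exposures E_a give a rate m_a = D_a/E_a, converted
to q_a = 1 − exp(−m_a·w_a) under a constant hazard within the segment,
and chained to ⁵q₀ = 1 − Π(1 − q_a). Zero exposure in a segment flags
the observation missing — unless the cohort has already been
exhausted (cumulative survival 0), or the segment has deaths with no
exposure (instantaneous mortality, q_a = 1), which arise in degenerate
fixtures. The SE is a leave-one-mother-out jackknife, respecting
within-mother correlation; leave-outs that empty a segment are skipped.

## Coverage trends

**Stage 1.** Per indicator, a linear mixed model on the transformed
scale with fixed effects [1, h₁(t), h₂(t)] and the same random effects
per region. h₁ is the centred linear term and h₂ the single curvature
basis of the natural cubic spline with boundary knots at the year-range
endpoints and one interior knot at the range midpoint (2000.5 for
1990–2011); both columns are rescaled to O(1) — fitted values are
invariant to this re-parameterization, but covariance estimation is far
better conditioned. Estimation is REML with an ML and then
fixed-effects-only OLS fallback; single-region inputs (including the
nation-pooled fit) go straight to OLS. When the estimated residual
variance is essentially zero (< 1e−10 of the response variance), the
random-effect predictions are replaced by their exact noiseless limit —
per-region least squares — instead of trusting the optimizer's final
shrinkage factor.

**Stage 2.** The region's stage-1 curve is the GP prior mean; the
covariance is Matérn with smoothness ν ∈ {1/2, 3/2, 5/2} (default 3/2 —
once-differentiable paths, a sensible middle ground for multi-year
health trends) and length-scale 10 years (roughly the spacing of two
survey rounds: trends are informative across neighbouring surveys but
not across the whole period). The posterior is exact Gaussian
conditioning; multiple observations in a region-year are kept as
separate heteroskedastic points. Each observation's noise is its
transformed-scale sampling variance plus a non-sampling floor.

**Amplitude and floor.** The stage-1 residual variance decomposes as
(mean sampling variance of the observations) + (excess variance due to
model misfit and source-level systematic error). That excess — floored
at 10% of the residual variance so the prior never fully collapses —
serves as both the prior amplitude² (how far the truth may wander from
the stage-1 mean) and the per-observation non-sampling floor. Using the
*total* residual variance here would double-count sampling noise and
produce intervals that essentially always cover; with the excess
decomposition, 95%-interval coverage on data simulated from the assumed
structure sits near 0.94–0.97. Both values are user-overridable, and a
marginal-likelihood optimisation flag is deliberately out of scope.

**Summaries.** 1,000 draws from the posterior Gaussian (eigenvalue
square root; negative roundoff eigenvalues clipped to zero),
back-transformed elementwise, summarised per year by median and
2.5th/97.5th percentiles. Back-transforming each draw keeps proportions
inside (0,1) by construction and lets the median commute with the
monotone transform up to quantile-interpolation error.

## Under-5 mortality model

Observed logit(⁵q₀) by region, year and source:

σ²-Normal likelihood around θ_its = β₀ + β₁t + β₂·1[s∉DHS] + uᵢ + vᵢt +
w_t + δ_it + γ_is, with time centred at the grid midpoint (decorrelates
intercept and slope; predictions unchanged). Priors: Normal(0, 31.6²)
on fixed effects; intrinsic CAR (graph-Laplacian structure) on u and v;
RW1 (second-difference structure) on w; their Kronecker product on δ
(null-space dimension n+T−1); iid Normal on γ; Gamma(1, 0.01) on every
precision including 1/σ². Sum-to-zero constraints hold for u, v, w and
both margins of δ.

**Sampling.** All mean components have one joint Gaussian full
conditional given the precisions, and every precision a conjugate gamma
conditional. The sampler updates the entire mean block at once in
Helmert contrast bases (u = B_n ũ with B_n orthonormal ⊥ 1, likewise w,
and δ = (B_T ⊗ B_n)δ̃), which makes the intrinsic priors proper on the
reduced coordinates and satisfies every constraint identically. The
joint update matters: one-at-a-time block updates mix pathologically
along likelihood-flat directions (the RW1 effect can trade a linear
trend against β₁ almost freely), while the joint conditional handles
those ridges exactly. Per iteration the dominant cost is one Cholesky
factorization of a (3 + 2(n−1) + (T−1) + (n−1)(T−1) + n·S)-dimensional
precision matrix — about 260×260 for 10 regions, 22 years, 3 sources —
a few milliseconds, so 2 chains × 5,000 iterations fit in ~10 s.

Chains start from zeros (intercept at the data mean, unit precisions);
the first half of each chain is burn-in by default. Split-R̂ is reported
for β₀, β₁, β₂ and the log precisions; values above 1.1 trigger a
warning to lengthen chains. Predictions exclude β₂ and γ: θ_it
quantiles are taken on the logit scale and inverse-logit transformed
(valid by monotonicity).

The model intentionally uses a single shared σ² as its observation
variance; per-observation sampling variances from birth-history
estimation are not part of the model (the source effects γ and σ²
absorb source-level noise).

## Benchmarking

The overall index is the unweighted mean of 11 components, with
underweight prevalence entering as its complement; equal weights keep
the index interpretable and avoid defending a weighting theory.
Index uncertainty averages *matched* posterior draws (draw d of the
index is the mean of the components' draw d), preserving within-draw
structure. Correlations are Pearson product-moment over pooled
region-year pairs by default (by-year or by-region pooling is a flag);
series with zero variance are rejected rather than returning NaN.

## Synthetic worlds: what they emulate, and what they don't

The generators reproduce the features the estimators rely on: 10
regions on a connected adjacency graph; 22-year grids; region-varying
logistic coverage trends strictly inside (0,1); multi-source survey
schedules with design-based sampling error scaled by effective sample
size; an additive non-DHS shift on the transformed scale; clustered
microdata whose cluster-level coverage is Beta-distributed with mean
equal to the truth (so intra-cluster correlation is induced without
biasing the population mean, which a logit-normal cluster effect would
do); birth histories whose piecewise-constant hazards are solved so the
implied ⁵q₀ equals the truth exactly, with censoring at the survey
date; and exact constrained draws from the mortality model via the
eigendecomposition of each structure matrix (components along null
directions dropped), so all sum-to-zero constraints hold by
construction.

They do **not** emulate: multi-stage designs beyond cluster PSUs,
stratification, or calibration weighting; recall error, misreported
ages or heaping; survey non-response; summary birth histories (only
complete histories are generated); question-comparability differences
between survey rounds; or migration between regions. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions — not robustness to the full messiness of real survey data.

Default generator settings are the study-like conditions used
throughout the tests: effective sample sizes near 1,000 per
region-year, a +0.3 logit non-DHS shift, five DHS-style survey years
plus one shifted source for coverage, three annual-series sources for
mortality, and mortality-model parameters (β₀ = −2.0, β₁ = −0.035 per
year, σ² = 0.01, precisions 50/5,000/400/500/100 for u/v/w/δ/γ) chosen
to produce mid-100s-per-1,000 mortality declining over the period with
region spreads of a few dozen per 1,000.

## Numerical choices

- Randomness: every simulator and chain draws from a named CRC-32
  substream of one master seed (`rng.stream_rng`), so reordering
  operations never changes any single result, and all outputs are
  bit-reproducible.
- GPR conditioning uses a Cholesky solve; a singular system gets one
  shot of 1e−8 jitter before failing.
- Posterior draw matrices use the symmetric eigenvalue square root with
  negative eigenvalues clipped at zero.
- Quantile interpolation: summaries use linear-interpolated percentiles;
  transform-commutation is exact only at order statistics.
- The 500-record birth-history oracle fixtures are quantized to dyadic
  birth dates and ages so weighted sums are exact in any summation
  order, enabling bitwise comparisons.
- `run_all` outputs carry a provenance header (config hash excluding
  the output path, plus the master seed) and no timestamps, so reruns
  are byte-identical.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes
chosen as representative of the study scale: 10 regions × 22 years
throughout; 220 region-year cells per recovery experiment; 20 replicate
mortality fits at 2 chains × 5,000 iterations for calibration; 50,000+
births for the ⁵q₀ consistency check; 1,000 posterior draws for
interval summaries.

## Limitations

- The packaged 10-region adjacency is an approximate digitization of a
  region map and is explicitly a stand-in; all spatial code accepts a
  user-supplied edge list.
- The Gibbs sampler assumes every observed region is in the graph and
  years lie on the grid; it does not handle missing-at-random region
  dropout specially (cells with no data are informed by the priors).
- GPR hyperparameters are fixed defaults, not learned; badly
  misspecified length-scales will show up as poor calibration.
- Indirect mortality estimation from summary birth histories is out of
  scope, as are survey designs beyond cluster PSUs.
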