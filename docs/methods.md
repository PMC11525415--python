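# Methods

This note documents the statistical procedures implemented in `nlsempower`,
the modeling choices made where the underlying ideas leave room, and what the
package's tests do and do not establish.

## Population model and simulation

A population QISEM is a recursive system: exogenous latent variables ξ with
covariance matrix Φ; structural equations η_k = α_k + Σ γ_kt t + ζ_k whose
terms t are latents or pairwise latent products (identical pair = quadratic);
indicators x = ν + λ·latent + ε. All parameters carry numeric population
values; all variances (Φ diagonal, residual ψ, error θ) must be stated,
covariances default to 0, means/intercepts default to 0. Simulation is
equation by equation: exogenous latents, residuals and errors are drawn
jointly multivariate normal, endogenous latents are built constructively with
products formed from realized (raw, uncentered) values. Endogenous variables
are therefore model-implied non-normal — their indicators show excess
kurtosis, which is why robust (sandwich) standard errors are used throughout.

Reproducibility: every replication uses a substream seed that depends only on
the master seed and the replication index (words of the master seed's entropy
stream), so serial and multi-process runs are bit-identical.

## Analytic moments

For centered jointly normal A, B, C, D the Isserlis identities give
E[AB] = Cov(A,B), Cov(AB, C) = 0 and
Cov(AB, CD) = Cov(A,C)Cov(B,D) + Cov(A,D)Cov(B,C). The moments module solves
the linear part of the structural system exactly and extends it with product
moments, yielding: implied variances of endogenous latents (γ'Σγ + ψ),
residual variances that standardize them to unit variance, sequential
explained-variance increments of product terms, and composite (sum-score)
scale reliability (Σλ)²V/((Σλ)²V + Σθ).

Two scope rules follow from the mathematics:

* a latent whose own equation contains product terms is non-normal; it may
  appear linearly downstream, but a product *of* such a latent has no
  closed-form moments here and is handled only by simulation;
* variance increments are defined sequentially in the order given (the
  increment of a term includes its covariances with previously added terms).
  Individual increments are order-dependent; their total is not. For the
  bundled moderated mediation model, adding ξ₁ξ₂ first gives 1.25% and then
  η₁ξ₁ gives 2.85% — the convention under which both printed effect sizes of
  that design are reproduced.

The identities assume centered components; the package's default zero means
make this exact. Declared nonzero means affect only the mean bookkeeping.

## Estimators

**SR.** Scale means per latent, centered; products of centered means;
recursive path model fitted per equation by OLS with HC1
(heteroskedasticity-consistent, finite-sample scaled) standard errors via
statsmodels. HC1 is a concrete choice where "robust standard errors" is
otherwise underdetermined. SR does not model measurement error: the
interaction estimate is attenuated roughly by the product of the component
reliabilities, and the tests assert the direction of that bias.

**FSR** (SL flavor). ML confirmatory factor analysis of the linear
measurement model (marker loading fixed to 1, latent covariances free;
single-indicator latents keep loading and error fixed at population values,
since they are otherwise unidentified). Regression (Thomson) scores
Φ̂Λ̂'Σ̂⁻¹x estimate the exogenous latents, Bartlett scores
(Λ̂'Θ̂⁻¹Λ̂)⁻¹Λ̂'Θ̂⁻¹x the endogenous ones; centered scores and their
products enter the same HC1 path regression.

**UPI.** Product indicators are built per latent product term — *matched*:
the i-th indicator of each component in declaration order (squares for
quadratic terms); *all*: the full cross product — and double-mean-centered
by default (components centered, product formed, product re-centered), which
removes the mean structure of the augmented model. The augmented linear SEM
frees all loadings (first per latent fixed to 1), all error variances,
structural slopes, endogenous residual variances, and the full covariance
block among exogenous latents and latent product factors; covariances
between product factors and structural residuals stay fixed at zero. Matched
pairing uses declaration order for determinism.

**fit_linear_sem.** The shared ML engine minimizes
F(θ) = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − p by L-BFGS with an exact analytic
gradient (each free parameter perturbs Σ by a rank-two update), followed by a
BFGS polish if the gradient norm exceeds 1e−4. Start values: loadings 1,
error variances half the indicator variance, latent variances half the
marker variance, structural coefficients 0; gradient tolerance 1e−8, 500
iterations. Nonconvergence, a non-invertible Hessian, or an improper
solution (negative variance estimate) is *flagged*, never raised, and flows
into the reported convergence rate. Standard errors are the sandwich
(H⁻¹ I H⁻¹)/n with H the numerical Hessian of the mean casewise objective
and I the empirical covariance of the exact casewise scores; under correct
specification and normality they agree with information-based errors (tested
at ratio 1 ± 0.1).

LMS (the distribution-analytic ML approach) requires external Mplus software;
the method name is recognized and refused with a clear error.

## Power model

Significance decisions: z = ϑ̂/SE(ϑ̂); one-sided tests are directional in the
sign of the population coefficient (S = 1 iff sign(ϑ₀)·z > q₁₋α), two-sided
use |z| > q₁₋α/₂. Nonconverged replications carry no decision and are
excluded from the power fit; their rate is reported separately.

The binary regression of S on √n (probit default, logit available) is fitted
by Newton iteration with step-halving on binomially aggregated data —
records share few distinct sample sizes, so aggregation makes each fit
essentially free; this matters because the search validation harness
performs tens of thousands of fits. The coefficient covariance is the
inverse observed information. The implementation is cross-checked against
statsmodels GLM in the test suite (coefficients to 1e−5). Complete
separation (all decisions equal, or a single distinct n) raises an explicit
error naming the remedy: widen the range of sample sizes.

Inversion: N_α = ⌈((Φ⁻¹(ρ) − β₀)/β₁)²⌉ (well-defined for β₁ > 0; values at
or below n = 1 return 1). Confidence bands are computed on the
linear-predictor scale with variance [1,√n]·V̂·[1,√n]' and transformed
through the link, keeping them inside (0, 1). N_α,lb is the smallest integer
n whose lower band reaches ρ, found by doubling plus bisection (the band is
monotone along n for β₁ > 0) under a documented ceiling of 10⁷. The
*continuous* crossing point (before the ceiling) is stored alongside: its
sampling distribution carries the nominal 1 − α_ρ/2 level, whereas the
integer ceiling makes the realized under-shoot rate conservative whenever a
single unit of n moves the power by a non-negligible fraction of its
standard error (small required sizes, large replication counts). The
validation metrics therefore report bias/RMSE on the integer recommendation
and the Type I (under-shoot) rate on the continuous crossing, with the
integer-based rate available as `type1_integer`.

## Sample-size search

**Brute force.** All R sizes drawn up front from [n_min, n_max],
systematically (an even grid, optionally with several replications per grid
point) or uniformly at random; one final power fit. Accurate when the
interval covers the required size, biased when it does not.

**Adaptive.** Step 1 draws on [n_start/2, 2·n_start] with defaults
n_start = 10·#par and lower bound n_lb = 5·#par (#par is the free-parameter
count of the fitted model — a standard minimum-sample heuristic for SEM).
Wide steps (before the switch step, default steps/2 of 10 steps) refit the
curve on all accumulated records and draw uniformly between the sizes whose
predicted power is .15 and .85; narrow steps draw between the n where the
*upper* band crosses ρ and the n where the *lower* band crosses ρ (one
faithful reading of "bounds around the target"). Intervals are clipped to
n_lb and, with constrained change (default), each endpoint may move by at
most a factor of 2 per step. Replication counts per step follow the
`increasing` allocation by default (R_j ∝ j; `equal` and `u_shaped`
∝ 1 + distance from the middle step are available). If an interim fit is
separated or has non-positive slope, the next step doubles the previous
interval instead; only separation at the final fit is an error. Uniform
integer draws realize "symmetrically distributed in the interval" — the
simplest symmetric law; intervals are constructed on the raw-n scale.

The decisions for multiple POIs are recorded jointly; interval selection
follows the POI currently requiring the largest n (the one that will decide
the final recommendation, which is the maximum of the per-POI N_α,lb).

The artificial backend replaces simulate-and-fit by S ~ Bernoulli(Φ(β₀+β₁√n))
and plugs into both drivers unchanged; it is the vehicle for validating the
search machinery itself at scale (a model-based backend is ~10³ times more
expensive per decision).

## Validation harness

`evaluate_search` repeats a configured search against a known reference
N_α and reports Bias = mean(N̂_lb − N_α), RMSE, relative bias, and the
under-shoot (Type I) rate; failed repeats are counted, never silently
dropped. `estimator_performance` aggregates batches of QISEM fits into
sample-size-weighted bias, relative bias (in percent, parameters with
population value 0 excluded), root weighted MSE, and the convergence rate;
scalar summaries are unweighted means over the structural coefficients (the
aggregation rule is a package choice; parameter-level values are always
available).

Benchmarks run in the acceptance tests at 2000 repeats of R = 10⁴ decisions
per condition — a scale chosen so the full suite completes on a single CPU
in well under half an hour while keeping the Monte-Carlo standard error of
the bias estimate near 0.1 (β₁ = .2) and 0.4 (β₁ = .1).

## Bundled study designs

`moderation_model()`: Eta1 ~ .2·Xi1 + .5·Xi2 + .1·Xi1:Xi2, unit-variance
predictors correlated .5, residual variance .5975 — the interaction explains
1.25% of the outcome variance. `moderated_mediation_model()`: the mediation
ξ₂→η₁→η₂ with ξ₁ moderating both paths into η₂ (coefficients
.2/.5 and .2/.1/.2/.3/.1), residual variances .61 and .620975 so every
latent has unit variance; increments 1.25% and 2.85%. Loadings are 1
throughout; per-item reliability is set by the error variance: "high" = .8
(θ = .25), "low" = .5 (θ = 1), "perfect" = error-free. These reliability
levels are package conventions for a design whose exact measurement
parameters are a free choice of the study planner.

## What the synthetic conditions do and do not show

Everything is multivariate normal on the exogenous side by construction, so
passing tests demonstrate correctness of the machinery under the model's own
assumptions — not robustness to non-normal predictors, ordered-categorical
indicators, missing data, or clustering, none of which the simulator
produces. The probit power law itself is an asymptotic statement: at very
small n (heavy nonconvergence) or extreme targets (ρ ≥ .99) the curve fit
degrades, which is why the search keeps sizes above n_lb and the
documentation recommends R ≥ 2000 (and 10–100× more for precise
requirements).

## Known limitations

* Only SR, FSR and UPI; no LMS (external software), no constrained product
  indicators, no two-stage method of moments.
* One- and two-sided z-tests of single coefficients; no tests of functions
  of parameters (indirect effects).
* Product terms of latents that are themselves nonlinear functions are
  simulable but outside the analytic moment engine.
* The measurement model is linear with uncorrelated-by-default errors;
  error covariances may be declared but cross-block covariances (e.g.,
  between a latent and an error) are rejected.
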