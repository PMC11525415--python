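# nlsempower

Simulation-based power estimation for structural equation models with latent
quadratic and interaction effects (QISEM) — latent moderation, moderated
mediation, and quadratic effects. For these models no analytic power formula
exists, yet interaction effects are typically small (a 1–3% variance
increment is realistic), so planning the sample size is exactly where it
matters most. This package is for methodologists and applied researchers who
need a defensible *required sample size* before collecting data.

## The method

Write the population model — every loading, structural coefficient and
(residual) variance set to a numeric value — in a lavaan-style text syntax.
For a sample of size *n* simulated from that population and fitted by one of
the supported estimators, the z-test of the parameter of interest ϑ (the
"POI", typically a latent interaction coefficient γ) is significant with a
probability that, by asymptotic normality of the estimator, follows a probit
curve in √n:

    P(S = 1 | n) = Φ(β₀ + β₁√n),      β₀ → −q₁₋α,  β₁ → |ϑ₀| / ω,

where ω is the asymptotic standard deviation of the estimator (the square
root of the relevant diagonal element of the sandwich covariance H⁻¹IH⁻¹).
Fitting this two-parameter curve to *all* simulated significance decisions
uses every replication — at whatever n it was run — and inverting it gives
the required sample size for target power ρ:

    N_α = ⌈((Φ⁻¹(ρ) − β₀) / β₁)²⌉.

Because β₀, β₁ are estimates, the recommendation is the conservative
**N_α,lb**: the smallest n whose *lower* confidence band reaches ρ, which is
at least N_α with probability ≈ 1 − α_ρ/2.

The replication sample sizes are chosen either on a user-given interval
(brute force) or by an **adaptive search**: a wide phase samples where
predicted power lies in [.15, .85] (the steep, informative part of the
curve), then a narrow phase concentrates around the target, with per-step
interval changes constrained so an unstable early fit cannot derail the run.

Three estimators for the QISEM are built in:

* **SR** — scale regression: scale means as single indicators, products of
  centered means, OLS path model with HC1 sandwich errors. Fast, but
  measurement error attenuates the interaction estimate.
* **FSR** — factor score regression: ML confirmatory factor model, then
  regression (Thomson) scores for exogenous and Bartlett scores for
  endogenous latents in the path model.
* **UPI** — unconstrained product indicators: matched, double-mean-centered
  indicator products measure each latent product factor; the augmented
  linear SEM is fitted by ML with sandwich standard errors.

(LMS, the distribution-analytic ML approach, needs external Mplus software
and is deliberately not included.)

## Worked example

Fit a power curve to 10 000 artificial significance decisions drawn from a
probit curve with β₀ = −1.64, β₁ = 0.2 (true required n for power .8: 154)
and invert it (`examples/03_power_curve_inversion.py`):

```
fitted power curve: beta0 = -1.6874, beta1 = +0.20519
required n for power .8:              N_alpha    = 152
conservative (lower-band) required n: N_alpha_lb = 156
  n= 100: power 0.642  [0.628, 0.657]
  n= 152: power 0.800  [0.791, 0.809]
  n= 156: power 0.809  [0.800, 0.818]
```

N_α is the point inversion; N_α,lb is where the lower band (bracketed
values) reaches .80 — the number you would put in a grant application. The
adaptive search drives the same machinery step by step
(`examples/04_adaptive_search.py`):

```
step     interval   R_j  interim N_alpha
   1 [  75,  300]   181                -
   2 [  50,  159]   363              142
   5 [ 141,  159]   909              149
  10 [ 151,  158]  1823              154
final N_alpha    = 155 (truth 154)
final N_alpha_lb = 158 (recommendation)
```

A full model-based analysis — simulate, fit, decide, invert — is three lines
(`examples/05_full_power_analysis.py`):

```python
from nlsempower import SearchConfig, moderation_model, run_mspe

spec = moderation_model("high")           # latent moderation, gamma = .1
config = SearchConfig(method="adaptive", R=1000, seed=2024)
result = run_mspe(spec, ["Eta1~Xi1:Xi2"], estimator="SR", config=config)
print(result.overall_n_alpha_lb)          # -> 405
```

The same workflow is available from the shell:

```bash
nlsempower run model.txt --poi "Eta1~Xi1:Xi2" --method SR --R 2000 --seed 2024
nlsempower reanalyze mspe_out/result.json --power-aim 0.9
```

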