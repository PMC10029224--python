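# Methods

## Scope and data model

The package analyzes participant-level tables of community-dwelling older
adults: sex, age, the five physical-frailty-phenotype (PFP) criterion
measures (habitual gait speed in m/s, maximal grip strength in kg, body
weight in kg and height in m, weekly walking hours, two 0–3 CES-D
exhaustion items), 36 frailty-index deficit items scored in [0, 1], and
one-year falls / hospitalization indicators. The frailty index (FI) is the
proportion of deficits present among observed items; an FI is treated as
missing when fewer than 30 of 36 items are observed (standard
deficit-accumulation practice; the minimum is configurable). FI classes use
inclusive upper bounds: robust ≤ 0.10 < prefrail ≤ 0.21 < frail.

Count-based PFP cut-points: slowness gait < 1.0 m/s; weakness grip < 28 kg
(men) / < 18 kg (women); shrinking BMI ≤ 18.5 kg/m² — the boundary is
inclusive by design here, with a `strict_shrinking` switch for the strict
variant; low activity walking < 2 h/week; exhaustion = either CES-D item at
level ≥ 2 ("a moderate amount of the time") on the 0–3 coding (0 rarely,
1 some, 2 a moderate amount, 3 most of the time).

## The beta regression

FI values (shrunk off the boundary by `(y(n-1)+0.5)/n`, the standard
adjustment when a proportion can attain 0 or 1 — fully robust subjects have
FI = 0) are modeled as Beta(μφ, (1−μ)φ) with logit(μ) a sum of

- thin-plate regression spline smooths of the standardized continuous
  criteria (walking time cube-rooted before standardization, damping its
  long right tail),
- monotonic ordinal effects for the CES-D items, and
- a linear sex term.

**Spline basis.** The 1-D thin-plate construction: the radial kernel
η(r) = |r|³ is evaluated between knots (the unique covariate values,
thinned to at most 200 quantile knots for economy), restricted to the
complement of the {1, x} null space, eigen-decomposed, and the leading
k − 2 eigenvectors retained with the wiggliness penalty rescaled to the
identity. The basis therefore contributes one unpenalized linear column and
k − 2 penalized columns (the constant is absorbed by the intercept);
penalized columns are residualized against [1, x] at training so they are
exactly orthogonal to the linear column, with the projection reapplied at
prediction time. Default basis size k = 10 per smooth (capped at one less
than the number of distinct values). Covariate values outside the training
range are evaluated by linear extrapolation of each basis function, with a
logged warning.

**Monotonic effects.** An ordinal predictor at level x contributes
b · Σ_{j≤x} ζ_j with ζ a simplex over the L − 1 level gaps, so the category
effects share one direction while each gap keeps its own size. Internally ζ
is parametrized by an additive-log-ratio transform whose Jacobian is
included in the posterior; every retained draw satisfies the simplex
constraint by construction.

**Priors** (predictors standardized, so one scale fits all): Normal(0, 2.5)
on linear and monotonic-scale coefficients and on the unpenalized linear
part of each smooth; Student-t(3, 0, 2.5) intercept; half-Student-t(3, 0,
2.5) on each smooth's SD τ; Dirichlet(1, …, 1) on each simplex;
Gamma(0.01, 0.01) on the precision φ. These are conventional weakly
informative defaults: prior draws of μ cover essentially all of (0, 1)
without collapsing.

**Sampling.** The posterior is smooth and moderate-dimensional (59
parameters for the full model), so the package uses a Hamiltonian Monte
Carlo sampler with analytic gradients: leapfrog integration, dual-averaging
step-size adaptation to a 0.8 acceptance target, a diagonal mass matrix
estimated from the middle warm-up window, and trajectory lengths jittered
up to `sim_length / step size` (default simulated length 4.0, at most 96
leapfrog steps). Smooth coefficients use the non-centered parametrization
(coefficients = τ · standard-normal effects), which removes the τ–effect
funnel that stalls centered samplers when a smooth is weakly identified.
Positive parameters (τ, φ) are sampled on the log scale with the Jacobian
included. Defaults are 4 chains × 3000 iterations with the first half
discarded as warm-up; a fit is flagged non-converged (logged warning,
`converged_ = False`) unless every parameter has split R-hat ≤ 1.01 and
bulk ESS ≥ 400 (computed with arviz). The reduced budgets used by the test
suite and the acceptance script (2 × 700 to 4 × 1000) trade the strict
contract for runtime; the orderings and recovery checks they assert are
insensitive to the remaining Monte-Carlo error, and the full default budget
satisfies the contract.

**Comparators.** The referent model enters the count-based PFP score as a
single linear (standardized) predictor — a `referent_linear=False` switch
fits it as a small smooth instead. The gait-speed model uses the same
spline machinery for age, weight and height as for gait speed, for
symmetry, plus linear sex.

## Validation

**PSIS-LOO.** Importance ratios 1/p(y_i|θ^s) per observation; the largest
M = min(0.2 S, 3 √S) log-ratios are replaced by expected order statistics
of a generalized Pareto distribution (GPD) fitted to the exceedances over
the M+1-th largest ratio, truncated at the raw maximum; weights are
self-normalized in log space. The GPD fit is the profile-likelihood
quantile-grid estimator with the usual light regularization of the shape
toward 0.5 (10 pseudo-observations). Shapes k > 0.7 flag an unreliable
observation without aborting. The implementation reproduces the reference
PSIS smoothing (arviz) to 1e-10 in the tests, and its pointwise ELPD agrees
with exact refit-LOO (quadrature over the two-parameter intercept-only
posterior) to under 0.05 on an n = 40 check.

**LOO-R²** is 1 − SSE_loo/SST with the importance-weighted LOO predictive
means; its interval is a Bayesian bootstrap (Dirichlet weights, fixed
internal seed) over the pointwise error terms. **Bayes R²** is the
per-draw explained variance over explained plus expected beta residual
variance mean(μ(1−μ)/(1+φ)). These are different functionals: on data that
are genuinely beta-distributed LOO-R² does not exceed the Bayes R² (tested),
but on the synthetic cohort — whose FI is a 36-item binomial-type mean, not
a beta variate — the model's variance formula can overstate residual noise
and the inequality is not guaranteed. **ELPD differences** are paired
pointwise sums with SE = sd × √n; |diff| > 2 SE is reported as decisive.
**Calibration** uses lowess (tricube local linear, span 2/3, 3 robustness
iterations) of observed on predicted FI, read against the identity line.

## Classification and prognosis

Quadratic weighted kappa (weights 1 − (i−j)²/(K−1)²) with the
Fleiss–Cohen–Everitt large-sample SE; AUROC as the Mann–Whitney statistic
with ties half-weighted and the DeLong placement-value variance; the DeLong
test for two correlated AUROCs; categorical NRI with event and non-event
components and Pencina-type asymptotic CIs ("up" = moving from the
low-risk to the high-risk predicted category between classifiers). The
reclassification event definition throughout is FI-defined
prefrailty/frailty (FI > 0.10). Outcome models are complete-case binary
logistic regressions (statsmodels IRLS behind the package interface;
perfect separation is flagged); nested models are compared with the
likelihood-ratio χ² test, and the added value of the model-based PFP is
summarized as 1 minus the variance ratio of linear predictors before vs
after adding it.

## Synthetic cohort

One scalar latent frailty factor z ~ N(0, 1) per subject drives everything:

- continuous measures are mean + sd·(ρ z + √(1−ρ²) ε) with loadings ρ
  (age +0.35, gait −0.65, grip −0.5, weight −0.15, height −0.05, cube-root
  walking −0.4) — marginal moments are exact by construction;
- grip, weight and height have sex-specific means chosen so the overall
  means match the published sample characteristics at 74% women;
- CES-D items follow an ordered logit on 0.9 z with thresholds solved (by
  Gauss–Hermite quadrature) to hit target marginal exceedance rates;
- each deficit item j is Bernoulli(logistic(c_j + s_j z)) with slopes
  0.4–0.8 and intercepts solved so the marginal prevalences are an 0.02–0.20
  grid whose mean — hence the population mean FI — is 0.11 exactly;
- outcomes are Bernoulli(logistic(a + b·FI)) with (a, b) set to give ~14%
  falls and ~12% hospitalization incidence;
- missingness is injected completely at random at per-variable rates in
  the 0.2–1.5% band (0.3% per deficit item), and both outcomes are jointly
  missing for a random 44% (follow-up completion 56%), independent of
  baseline.

What the generator does *not* emulate: instrument-specific measurement
error, the real items behind the 36 exchangeable deficits, informative loss
to follow-up, multi-factor frailty structure, or sharp threshold effects in
predictor–FI relations. Passing the ordering checks (LOO-R²
model-based > gait-speed > referent; model-based kappa and AUROC above
count-based) therefore demonstrates that the pipeline detects the
information lost to dichotomization under a realistic correlation
structure — not that the published effect sizes transfer to any particular
real cohort.

## Numerical choices and degenerate inputs

- Boundary FI values must be shrunk before fitting; the likelihood rejects
  y ∈ {0, 1}.
- μ is clipped to [1e-10, 1−1e-10] inside the sampler for numerical safety.
- Zero-variance predictors, all-missing imputation targets, single-class
  outcomes, constant calibration predictions and degenerate (spread-free)
  GPD tails are rejected with named errors rather than silently handled.
- Imputation is chained OLS with predictive-mean matching (5 donors, 3
  cycles, seeded), adequate at per-mille missingness; imputed values are
  always observed donor values, so ordinal items stay on their grid.
- Fixed seeds make every stage bit-reproducible: cohort generation,
  imputation donors, HMC chains (per-chain seeds spawned from one
  SeedSequence), and the bootstrap interval inside LOO-R².

## Problem sizes

The default study size is n = 998 participants. The test suite and the
acceptance script fit MCMC at reduced budgets (2 × 700 for the shared
ordering fixtures, 2 × 800 for parameter recovery, 4 × 1000 in the
acceptance script) and use n = 40 for the exact-refit LOO oracle, 10⁴ draws
for GPD shape recovery, and n = 400 for the pipeline smoke run; these are
the package's own choices of problem size for routine verification, with
the full 4 × 3000 budget available via configuration.
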