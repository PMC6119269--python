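# Methods

## Model

For case *i* with outcome *Yᵢ*, outcome covariates *Xᵢ* and selection
covariates *Xˢᵢ*, the sample-selection (Tobit type-2) model couples a probit
selection equation for the observedness indicator *Rᵢ* (1 = observed) with the
outcome equation through bivariate-normal latent errors:

- selection: `R'ᵢ = Xˢᵢ βˢ + εˢᵢ`, `Rᵢ = 1{R'ᵢ > 0}`, `Var(εˢ) = 1`
- binary outcome: `Y'ᵢ = Xᵢ β + εᵢ`, `Yᵢ = 1{Y'ᵢ > 0}`, `Var(ε) = 1`,
  `Corr(εˢ, ε) = ρ`
- continuous outcome: `Yᵢ = Xᵢ β + εᵢ`, `Var(ε) = σ_ε²`, `Cov(εˢ, ε) = ρσ_ε`
  (the off-diagonal is ρσ_ε and the error variance σ_ε², as dimensional
  consistency requires)

`ρ = 0` is MAR given covariates; `ρ ≠ 0` is MNAR. Intercepts are always
included in both linear predictors and never listed in covariate sets. The
selection equation should contain at least one covariate absent from the
outcome equation (exclusion restriction); a specification that violates this
is accepted with a warning, since identification then rests only on the
nonlinearity of the inverse Mills ratio.

## Estimation

**One-step ML (binary).** The joint bivariate-probit log-likelihood

```
l = Σ_{R=0} log Φ(−Xˢβˢ) + Σ_{R=1,Y=1} log Φ₂(Xβ, Xˢβˢ, ρ)
                         + Σ_{R=1,Y=0} log Φ₂(−Xβ, Xˢβˢ, −ρ)
```

is maximised over the unconstrained vector θ = (β, βˢ, atanh ρ). Φ₂ is
evaluated through Owen's T function (closed forms at zero thresholds and
|ρ| = 1), accurate to ~1e-14 — the unit tests verify it against independent
2-D adaptive quadrature. Analytic gradients are used throughout and are
verified against finite differences.

**One-step ML (continuous).** The likelihood combines the probit factor for
non-selected cases with, for selected cases, the Gaussian density of *Y* and
the conditional-probit factor `Φ((Xˢβˢ + (ρ/σ_ε)(Y−Xβ))/√(1−ρ²))`; θ gains a
`log σ_ε` component.

**Two-step (Heckit; continuous only).** Step 1 is a probit of *R* on *Xˢ*;
step 2 an OLS of *Y* on (X, λ̂) over observed cases, with
λ̂ᵢ = φ(Xˢβ̂ˢ)/Φ(Xˢβ̂ˢ) the inverse Mills ratio. σ̂_ε² is recovered as
`e'e/n₁ + β̂_λ² · mean(δᵢ)` with `δᵢ = λ̂ᵢ(λ̂ᵢ + Xˢβ̂ˢ)`, and ρ̂ = β̂_λ/σ̂_ε.
The reported covariance is deliberately *uncorrected*: the step-2 OLS
covariance treats λ̂ as known, so first-step uncertainty is not propagated.
This preserves the recognised weakness of the two-step estimator that the
one-step ML approach is meant to fix; no Murphy–Topel correction is offered.
For a binary outcome the two-step construction is statistically invalid
(selection does not enter a probit as an additive regressor) and the package
refuses it with an explicit error rather than implementing it.

**Covariance Ψ̂.** Stored on the unconstrained scale so that Gaussian
parameter draws always back-transform to `|ρ*| < 1`, `σ* > 0`. The default is
the inverse *observed* information, obtained by central finite differences of
the analytic gradient (relative step 1e-5), symmetrised, with eigenvalues
floored at 1e-10 before inversion. Inside the chained-equations loop the
outer-product-of-gradients (BHHH) estimate — one vectorised evaluation of the
per-case scores — replaces the finite-difference Hessian; the two are
asymptotically equivalent and the OPG variant cuts the cost of a visit
roughly in half. The two-step Ψ̂ maps the step-2 covariance of (β, β_λ) onto
(β, atanh ρ, log σ) by a numerically differentiated delta method, with the
step-1 probit covariance in the βˢ block and zero cross-blocks.

**Optimiser.** BFGS with the analytic gradient; maximum 500 iterations;
gradient tolerance 1e-6 (measurements showed 1e-8 changes θ̂ by < 1e-7 while
triggering spurious line-search "precision loss" restarts). Start values:
βˢ from a probit of R on Xˢ, β from a probit/least-squares fit on observed
cases, ρ = 0, σ_ε from the residual SD. On failure the fit restarts once from
deterministically perturbed start values. Warm starts (previous θ̂ and Ψ̂ as
the quasi-Newton seed, eigenvalue-clipped) accelerate repeated fits inside
MICE. |atanh ρ̂| is capped at 5 (|ρ̂| < 0.9999): a direct fit that hits the
cap is flagged non-convergent, because Ψ̂ degenerates at the boundary.

## Imputation

Proper imputation of an MNAR outcome proceeds per pass:

1. fit the selection model by one-step ML (or two-step, continuous only);
2. draw θ* ~ N(θ̂, Ψ̂) on the unconstrained scale via an eigendecomposition
   of Ψ̂ — one draw per imputed dataset per variable per iteration, shared by
   all missing cases of the pass, redrawn each iteration;
3. impute each missing case from its missing-case conditional law:
   binary `Y* ~ Bernoulli(Φ₂(Xβ*, −Xˢβˢ*, −ρ*) / Φ(−Xˢβˢ*))` (computed in
   log space with a 1e-300 floor before the final ratio, clamped to [0,1]);
   continuous `Y* = Xβ* + ρ*σ*(−φ(Xˢβˢ*))/Φ(−Xˢβˢ*) + N(0, σ*²)` with fresh
   noise per case.

At ρ = 0 both reduce exactly to their MAR counterparts (asserted in tests).
MAR predictors use the standard proper imputers: Bayesian linear regression
(σ*² from a scaled inverse-χ², β* from its conditional normal) and
logistic/probit regression with a normal parameter draw (default link logit;
probit selectable). Complete separation in the binary imputer falls back to a
Jeffreys-prior (Firth) penalised logistic fit with a logged warning.

## Chained equations

`multiple_impute` runs m independent chains, each on an RNG substream spawned
from the configured seed, so results are bit-reproducible for fixed
(seed, m, iterations, visit order). Each chain: initial fill by resampling
observed values; then per iteration, per incomplete variable (default order:
column order), the conditional model is re-estimated on the currently
completed data and the originally-missing cells are overwritten. The Heckman
selection response is always the *original* missingness indicator, which is
also appended as a permanent `R_<var>` auxiliary column; MAR predictor models
default to all other variables and are always augmented with each MNAR
outcome and its indicator. Default iterations = 20 (at least 10 recommended
for chains with incomplete predictors); with only the outcome incomplete the
conditional model does not depend on earlier fills and one iteration is
already exact.

A bivariate-probit correlation MLE occasionally sits on the |ρ| → 1 boundary
for particular chain states at n = 500 (profile-likelihood inspection of
captured cases shows gains of < 0.5 log-likelihood units beyond ρ ≈ 0.96).
Aborting such chains would discard a non-trivial share of replicates, so
after the warm- and cold-started unbounded fits both fail, the visit refits
with atanh ρ bounded at the cap (L-BFGS-B) and imputes from the constrained
optimum. Chains that still fail abort; `multiple_impute` is strict by default
(any aborted chain fails the whole set) so that simulation metrics are never
silently computed on a biased subset; a lenient mode returns the surviving
chains with a warning.

**Pooling.** Estimates and variances from the m completed-data analyses are
combined as q̄ = mean, W = mean within-variance, B = between-variance
(ddof = 1), T = W + (1 + 1/m)B, with Barnard–Rubin small-sample degrees of
freedom ν_adj = (1/ν_old + 1/ν_obs)⁻¹, ν_old = (m−1)(1 + W/((1+1/m)B))²,
ν_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1−γ), γ = (1+1/m)B/T; B = 0 falls back
to ν_com. 95% intervals use the t quantile at ν_adj.

## Synthetic data

The generators emulate a trial-like setting: X₁, X₂, X₃ ~ N(0, σ² = 0.5);
outcome coefficients β = (0, 1, 1) (binary prevalence 0.5; continuous
σ_ε = 1); selection coefficients βˢ = (0.75, 1, −0.5, 1) with X₃ the
exclusion-restriction variable, giving Φ(−0.75/√2.125) ≈ 30.3% missing
outcomes; ρ ∈ {0, 0.3, 0.6} spans MAR to strong MNAR; n = 500 per dataset,
1000 replicates by default. A robustness mechanism draws R from a logistic
model that includes Y itself (coefficients 1, −0.5, 1 on X₁, X₂, X₃ and
β_Y ∈ {0, 1, 2}; intercepts 0.60/0.20 binary and 1.31/1.86 continuous for
β_Y = 1/2, calibrated at β_Y = 0) — MNAR but incompatible with the selection
model, so some residual bias is expected there. Two MAR mechanisms delete X₂:
`R₂ ~ Bernoulli(Φ(c + X₁ + X₃))` (mechanism A) and
`R₂ ~ Bernoulli(Φ(c + X₁ + Y))` with the *pre-deletion* Y (mechanism B).

The conventional constants for the X₂ mechanisms (A: 0.25; B: 1.10 binary /
0.25 continuous) are analytically inconsistent with the ~30% missing-X₂
operating point the design describes — mechanism A at c = 0.25 gives
Φ(−0.25/√2) ≈ 43% missing. Both options are implemented: the default policy
calibrates c to the 30% target (mechanism A has the closed form
c = √2·Φ⁻¹(0.7) ≈ 0.742; the others use a Monte-Carlo root-find on a large
draw), and `intercepts="printed"` / `--intercepts printed` selects the
conventional constants.

What the generator does *not* emulate: covariate measurement error,
non-Gaussian or heteroscedastic errors, non-probit selection (except the
logistic robustness arm), clustered or longitudinal structure, or more than
one MNAR variable. Passing tests therefore demonstrate correctness of the
machinery and its behaviour under the stated bivariate-normal selection
model, not robustness to arbitrary real-data violations; assigning a Heckman
method to a *predictor* is possible but experimental and unvalidated.

## Evaluation harness

`run_scenario` applies, per replicate, any subset of: the pre-deletion
benchmark fit (`before`), complete-case analysis (`CCA`), direct
selection-model fits on complete-predictor cases (`HEml`, `HE2steps`), and
chained-equations multiple imputation (`MIHEml`, `MIHE2steps`) followed by
the probit/OLS analysis of Y on (X₁, X₂) and Rubin pooling. Per method and
coefficient it reports percent relative bias (100·(mean β̂ − β)/β), SE_cal
(root-mean-square of estimated SEs), SE_emp (Monte-Carlo SD of β̂), RMSE and
95%-CI coverage (Wald intervals for direct fits, t with Barnard–Rubin df for
pooled fits). Non-convergent replicates are excluded and counted. RNG
discipline: one master seed, per-replicate substreams, so every method sees
identical data within a replicate; when several scenario levels (ρ values)
are compared, they are run on common random numbers — the same substreams,
hence the same covariate and error draws transformed per level — which
leaves each level's marginal distribution untouched while keeping
across-level comparisons (and maxima over levels) from compounding
independent Monte-Carlo noise.

Problem sizes used by the packaged checks: the direct-estimator comparisons
run at the full 1000 replicates; the chained-equations scenarios with missing
X₂ run at 200 replicates with m = 10 and 10 iterations, and the MAR coverage
check at 500 replicates — scales at which the Monte-Carlo error of a bias
estimate is ~1 percentage point, sufficient for the bounds being checked.
`reproduce-table` accepts `--reps/--m/--iterations` to run any table at full
scale.

## Known limitations

- Ψ̂ from the OPG estimate inside chains is first-order equivalent to the
  observed information but can differ at small n; the direct estimators
  always report the finite-difference observed information.
- Boundary-ρ visits impute from a constrained optimum with a degenerate-
  direction Ψ̂ (eigenvalue-floored); their influence washes out across
  iterations and chains but single completed datasets from such passes are
  extreme.
- Two-step SEs are intentionally uncorrected (see above).
- The chained-equations procedure inherits MICE's general caveat: the
  conditionals need not correspond to any joint model; its validity here is
  established by simulation, not theory.
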