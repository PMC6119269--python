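# heckmice

Sample-selection (Heckman) models as imputation engines for outcomes that are
**missing not at random (MNAR)**, inside a **multiple imputation by chained
equations (MICE)** procedure — with the full simulation machinery to evaluate
them.

## The problem

In clinical studies an outcome is often missing for reasons related to its own
unseen value: patients who stop treatment are the ones least likely to report
adherence. Standard imputation assumes missing-at-random (MAR) and is biased
in that setting. A sample-selection (Tobit type-2) model instead couples the
analysis outcome with a probit model for its missingness indicator
`R` (`R = 1` ⇔ observed) through correlated bivariate-normal latent errors:

```
R'_i = Xs_i βs + εs_i          (selection equation, probit)
Y'_i = X_i  β  + ε_i           (outcome equation)
(εs, ε) ~ N₂(0, [[1, ρ],[ρ, 1]])        (binary Y: Y = 1{Y' > 0})
(εs, ε) ~ N₂(0, [[1, ρσ],[ρσ, σ²]])     (continuous Y)
```

`ρ = 0` is MAR; `ρ ≠ 0` makes missingness depend on the unobserved outcome.
For a **binary** outcome the parameters must be estimated by one-step maximum
likelihood of the joint bivariate probit (a two-step "inverse Mills ratio in a
probit" is invalid and this package refuses it). For a **continuous** outcome
both one-step ML and the classical two-step (Heckit) estimator are provided.

The package turns the fitted selection model into a *proper* imputation
engine: draw θ\* ~ N(θ̂, Ψ̂) on an unconstrained scale, then draw each missing
outcome from its missing-case conditional distribution

```
P(Y=1 | X, Xs, R=0) = Φ₂(Xβ*, −Xsβs*, −ρ*) / Φ(−Xsβs*)           (binary)
Y* = Xβ* + ρ*σ* · (−φ(Xsβs*))/Φ(−Xsβs*) + N(0, σ*²)              (continuous)
```

Because this is a conditional imputation model, it slots into a chained-
equations run next to ordinary MAR imputers (Bayesian linear, logistic/probit)
for incomplete predictors; estimates from the m completed datasets are pooled
with Rubin's rules using Barnard–Rubin small-sample degrees of freedom.

## Who it is for

Biostatisticians and epidemiologists analysing case-by-variable tables with a
suspected-MNAR binary or continuous outcome plus MAR predictors — or running
sensitivity analyses against the MAR assumption — and methodologists who want
the accompanying simulation study (data generators, comparator estimators,
bias/SE/coverage metrics) as a reusable harness.

## Worked example

Simulate one dataset under a strong-MNAR selection mechanism (ρ = 0.6, ~30%
missing outcomes), fit the bivariate-probit selection model, then multiply
impute and pool:

```python
import numpy as np
import heckmice as hm

cfg = hm.ScenarioConfig(outcome_kind="binary", rho=0.6, n=500)
sim = hm.gen_heckman_scenario(cfg, np.random.default_rng(7))

spec = hm.HeckmanSpec(outcome_var="Y", outcome_covars=["X1", "X2"],
                      selection_covars=["X1", "X2", "X3"],
                      outcome_kind="binary")
fit = hm.fit_heckman_ml(sim.observed, spec)
print(fit.summary().to_string(index=False, float_format="%.3f".__mod__))

methods = {"Y": hm.ImputationMethod(kind="heckman-binary", spec=spec)}
chain = hm.ChainConfig(methods=methods, m=20, iterations=5, seed=7)
imputed = hm.multiple_impute(sim.observed, chain)
pooled = hm.pool_analysis(imputed, hm.AnalysisModel("Y", ["X1", "X2"], "binary"))
print(pooled.to_string(index=False, float_format="%.3f".__mod__))
```

Output:

```
        term  estimate    se      z  ci_low  ci_high
 (Intercept)    -0.030 0.105 -0.286  -0.235    0.175
          X1     0.902 0.125  7.246   0.658    1.146
          X2     0.897 0.156  5.750   0.591    1.203
s(Intercept)     0.873 0.084 10.420   0.708    1.037
       s(X1)     1.270 0.136  9.332   1.003    1.537
       s(X2)    -0.570 0.109 -5.220  -0.784   -0.356
       s(X3)     0.980 0.117  8.396   0.751    1.208
         rho     0.845 0.144  5.868   0.563    1.127
       term  estimate    se      df  ci_low  ci_high
(Intercept)    -0.035 0.105  37.586  -0.246    0.177
         X1     0.889 0.120 149.334   0.653    1.125
         X2     0.885 0.151  56.290   0.583    1.187
```

The generating values are β = (0, 1, 1) and βs = (0.75, 1, −0.5, 1). Despite
30% MNAR missingness the outcome-equation slopes are recovered near 1 — on
this same replicate a plain complete-case probit gives β̂₁ = 0.65, a 35%
downward bias — the selection coefficients track the missingness mechanism,
and ρ̂ = 0.85 (SE 0.14) detects the selection effect. The pooled MICE
analysis (second table) reproduces the selection-model slopes with its
uncertainty widened by the Barnard–Rubin degrees of freedom.

A command-line interface wraps the same operations
(`heckmice fit | impute | simulate | reproduce-table | make-fixture`); e.g.

```bash
heckmice simulate --outcome continuous --rho 0.6 --reps 1000 --n 500 \
    --methods before,CCA,HEml,MIHEml --seed 1 --out table2_rho06.csv
heckmice reproduce-table 1 --reps 200 --m 10 --iterations 10 --seed 1
```

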