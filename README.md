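# poolsim

Monte-Carlo evaluation of **bio-specimen pooling designs** for epidemiological
studies with mismeasured exposures and an uncertainly ascertained dichotomous
outcome — the setting of an enriched-risk pregnancy cohort studying
environmental risk factors for autism spectrum disorders.

Pooling physically combines bio-samples from *g* participants and analyzes the
mixture as one laboratory sample, cutting assay costs by a factor of *g*.
Statistically, the pool-level covariate is the **sum** of the members' values,
and — following the Weinberg–Umbach set-based design — pools are formed within
strata of sex × case status, so each pool has a well-defined binary outcome.
`poolsim` asks what this design costs in **power**, what it buys in
**false-positive rate (FPR)**, and what it does to **bias**, when

* exposures carry classical measurement error, `W = X + ε`, `ε ~ N(0, σ²)`;
* the outcome is an integer screening score (AOSI-like, 0–18) dichotomized at
  ≥ 7, i.e. the true phenotype is observed with rounding/classification error;
* the true dose-response may be non-linear (threshold or saturation shapes).

## The simulation in brief

A cohort of 10⁶ children is generated with sex `Z ~ Bernoulli(0.5)`,
gestational age `X_ga ~ 43 − χ²(3)` weeks (1 week subtracted for 5% of boys),
and standard-normal exposures `X₁` (causal) and `X₂` (non-causal) with
Pearson ρ = 0.7.  The latent phenotype is

    Y = m(X₁)·β₁X₁ + β₂X₂ + β₃Z + β₄X_ga + ε_y,   ε_y ~ N(0,1)

with `β₂ = 0`, `β₃ = 1`, `β₄ = 0.1`/week, and slope multiplier `m(X₁)`
implementing the linear / threshold / saturation shapes around an inflection
at one SD below the exposure mean.  `Y` is mapped monotonically to a
log-normal score scale, rounded to an integer 0–18, and dichotomized at ≥ 7;
out-of-range gestational weeks or scores mark a record non-viable.

Each scenario draws 1000 replicate cohorts by stratified sampling (10
male-control, 18 female-control, 12 male-case, 5 female-case pools of size
*g*; 45 pools, cohort n = 45·g), and fits the pooled logistic model

    logit P(case pool) = c₀ + c₁ΣW₁ + c₂ΣW₂ + c₃ΣZ + c₄ΣW_ga + ln(r_z)

where `ln(r_z)` is the fixed case:control pool-ratio offset for sex z
(ln 12/10 for males, ln 5/18 for females) correcting for outcome-dependent
sampling.  Replicates are summarized by power (share of replicates with OR₁
significant at α = 0.05 or outside [0.1, 10]), FPR (same rule on OR₂), bias
(mean stable-replicate OR₁ over the population-truth OR₁), and the percent
mean change between pooled and paired individual-level analyses.

## Worked example

```sh
poolsim run-scenario --model linear --beta1 0.25 --me-var 0.0625 \
    --pool-size 5 --replicates 200 --pop-size 200000 --seed 11
```

prints (one summary row; wall time a few seconds):

```
 model  cohort_size  pool_size  eor1  beta1  me_variance  power_pct  bias_or1  fpr_pct  ...  n_stable  n_replicates  or1_population
linear          225          5   2.0   0.25       0.0625       64.5  1.319712      4.5  ...       190           200        1.777392
```

Reading: with a moderate causal effect (design OR 2, i.e. β₁ = 0.25) and good
assay precision (error variance 6% of the exposure variance), 45 pools of 5
detect the causal exposure in 64.5% of replicates, the correlated non-causal
exposure is flagged at roughly the nominal 4.5%, and the mean stable-replicate
OR₁ overshoots the population-truth OR (1.78 per exposure SD) by ~32% —
small-sample inflation of a 45-observation logistic fit.

Other entry points: `poolsim run-grid` (the full 108-scenario factorial),
`poolsim run-table3` (same-replicate comparison of pool sizes 1/5/15 at
n = 675), `poolsim simulate-population`, `poolsim calibrate-aosi` (the
scripted score-transform calibration; see `docs/methods.md`), and a YAML
`--config` mirroring every parameter (`poolsim.config`).

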