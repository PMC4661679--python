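# Methods

## Generative model

One simulated child carries truth values, observed values, and outcome
fields.  Truth: sex `z ~ Bernoulli(0.5)`; gestational age
`x_ga = 43 − χ²(3)` weeks, with one week subtracted for a simple random 5% of
boys (drawn after the χ² deviate; truth values are not re-truncated); causal
exposure `x₁` and non-causal exposure `x₂` jointly standard normal with
Pearson correlation 0.7 (Cholesky construction).  Observation: classical
errors `w_i = x_i + ε_i`, `ε_i ~ N(0, σ²_i)`, mutually independent and
independent of all truth fields; `σ²₁ ∈ {0.0625, 0.25, 1}` spans assay error
from 6% of the exposure variance to error as large as the signal, and
`σ²₂ = 0.25` is fixed.  Gestational age is additionally reported in completed
weeks: `w_ga = round(x_ga + ε_ga)`, `ε_ga ~ N(0, σ²_ga)`, and records outside
23–43 weeks are dropped (non-viable).  `σ²_ga` defaults to 1.72 weeks²; a
clamp-to-range alternative to dropping is available but off by default.

Rounding everywhere uses *half away from zero* (22.5 → 23, −0.5 → −1), the
convention of reported gestational weeks and integer screening scores;
`numpy`'s half-to-even would differ on exact halves.

## Latent outcome and dose-response shapes

`y = m(x₁)·β₁x₁ + β₂x₂ + β₃z + β₄x_ga + ε_y` with `ε_y ~ N(0,1)`, `β₂ = 0`,
`β₃ = 1` (male excess risk), `β₄ = 0.1` per week.  The slope multiplier
`m(x₁)` is selected by comparing `x₁` with an inflection point at one SD
below the exposure mean (−1): linear (1, 1), threshold (0, 1.5), saturation
(1.5, 0.5) for (below, at-or-above).  The piecewise forms are applied exactly
as written — the latent value jumps at the inflection (e.g. the saturation
contribution steps from −1.5β₁ to −0.5β₁ at x₁ = −1) — and the boundary
point uses the upper branch.  A continuous hinge variant exists behind
`continuous_piecewise` (off by default).

Effect sizes `β₁ ∈ {0.15, 0.25, 0.5}` are labelled by the odds ratio obtained
when `x₁` and the linear-model `y` are each dichotomized at one SD above
their means.  Exact quadrature over the generative law gives design ORs
1.518, 1.972 and 3.583; the conventional labels 1.5 / 2 / 4 are rounded
(the strong-effect label noticeably so), and `expected_or_check` reproduces
the exact values by simulation.

## Score transform and case definition

The latent phenotype is mapped to an AOSI-like integer scale: standardize
`y` by its scenario-level mean and SD, then
`score = exp(meanlog + sdlog·z)` — the log-normal quantile map under a normal
working assumption for `y`; since `y` is a normal mixture dominated by its
N(0,1) residual, the realized score margin tracks the target log-normal tail
to within ±0.005 (verified against the closed-form tail at n = 10⁶ for all
three dose-response shapes).  A rank-based `empirical` variant reproduces the
log-normal margin exactly regardless of the latent shape.  The continuous
score is rounded; integer scores outside 0–18 mark the record non-viable;
case status is score ≥ 7.  Because rounding commutes with the cutoff
(score ≥ 7 iff continuous score ≥ 6.5), the case margin is governed entirely
by `z_cut = (ln 6.5 − meanlog)/sdlog`.

**Calibration.**  The log-normal target (meanlog, sdlog) is not identifiable
from the design alone — it stands in for "match the observed score
distribution" in the motivating cohort.  It is pinned by one reference
quantity: the no-measurement-error pooled power for the linear model, weak
effect, cohort 225 with pools of 5 must land in 26.3–27.5%.  The scripted
step (`poolsim calibrate-aosi`: population 10⁶, 1000 replicates, seed 3)
scans the grid and freezes **meanlog = 0.9, sdlog = 0.5**, giving truth power
27.4% (in band), case prevalence ≈ 2.6% (in line with ASD-like prevalence),
median score ≈ 2.5, and a population logistic OR ≈ 1.40 per exposure SD at
the weak effect.  Estimated power carries replicate-level Monte-Carlo error
(±1.4 points at 1000 replicates) *and* population-level variation (±2 points
across population seeds), so the calibration band is meaningful only at the
protocol's fixed conditions; the parameters were frozen once and all other
results are computed at that operating point.

## Sampling, pooling, offsets

The viable population is stratified by sex × case status.  Each replicate
draws a simple random sample without replacement per stratum sized to the
allocation (10/18/12/5 pools × g members; an integer `scale` multiplies all
four counts, e.g. scale 3 with g = 5 realizes the 675-child cohort with 135
pools while preserving stratum proportions and offsets).  Within a stratum
members are partitioned uniformly at random into pools of exactly g; pool
covariates are sums; every pool carries the offset `ln(case pools / control
pools)` of its sex.  Pool size 1 reduces exactly to the individual-level
analysis with the same design offsets (tested to 10⁻⁶).  In the
pool-size-ladder comparison (1/5/15 at n = 675) the *same* sampled cohort is
re-partitioned independently for each pool size, per replicate.

## Estimation

The five-parameter logistic models (intercept + ΣW₁ + ΣW₂ + ΣZ + ΣW_ga, fixed
offset) are fitted by Newton–Raphson/IRLS written in-package, because the
iteration cap and failure semantics are part of the study's accounting:
convergence is a relative log-likelihood change < 10⁻⁸ within 50 iterations
(a gradient-norm criterion is selectable), one extra Newton step after the
criterion polishes the score equations to near machine precision, perfect
separation yields a *non-converged* result with the last iterate's (possibly
huge) odds ratios retained — extreme ORs count toward power/FPR numerators —
and a rank-deficient design raises.  Wald standard errors come from the
inverse observed information.  The fitter agrees with an independent GLM
implementation to 10⁻⁶ on reference designs.  A replicate is *stable* iff it
converged and both exposure ORs are strictly inside (0.1, 10); unstable
replicates stay in power/FPR denominators and numerators (via the extreme-OR
rule) but are excluded from bias and mean-OR summaries.  The bias denominator
is the individual-level logistic fit on the full viable population with true
covariates.

## Scenario orchestration and reproducibility

A scenario = dose-response shape × β₁ × (σ²₁ or error-free truth variant) ×
pool size; the full factorial grid is 108 scenarios.  Each scenario
regenerates a fresh population (matching the reference design, where each
measurement-error scenario drew its own viable population); the truth
variant fits replicate models with the error-free exposures and true
gestational age, while viability always uses the reported, rounded weeks.
Seeding: a scenario's `SeedSequence` (derived from a root seed and a CRC-32
hash of the design cell, kept below 2³¹) is split statelessly into
population / exposure-error / gestational-error / outcome-noise streams plus
one child per replicate, so any table cell is reproducible in isolation,
re-running a spec object is bit-identical, and replicates may be evaluated
in any order (the loop itself is sequential).

## Problem sizes

Defaults follow the reference design: population 10⁶, 1000 replicates.  At
these sizes one pooled scenario (generation + truth fit + 1000 sample/pool/
fit replicates) takes ~3 s on one CPU and the full acceptance recomputation
~30 s; the test suite uses populations of 4×10⁴–10⁶ depending on what each
check needs.  `--pop-size` overrides population size; 2×10⁵ is ample for
every stratum at n = 675.

## What the generator does and does not emulate

It emulates: realistic gestational-age skew with a male shift; correlated
exposures with classical, conditionally independent errors; outcome
ascertainment through a bounded integer screen with rounding and cutoff
misclassification; outcome-dependent stratified sampling with fixed
laboratory budget (constant pool count).  It does **not** emulate: real
gestational-age structure by parity/plurality; skewed exposure distributions
(e.g. lipophilic pollutant concentrations); pool-construction or assay error
at the pool level (errors are individual-level by design); unequal pool
sizes; more than two stratification variables.  Passing tests therefore
speak to the *design arithmetic and estimation machinery* under this
idealized cohort, not to any particular real assay.

## Known limitations

* With strong effects and large pools (design OR 4, g = 15) most replicates
  separate; summaries conditional on stability then average over few
  replicates and are sensitive to the stability rule.
* The percent-mean-change statistic divides by the total replicate count
  while summing only over qualifying replicates, following the conventional
  printed formula; it is therefore attenuated when many replicates are
  unstable.
* Population-level Monte-Carlo variation (one population per scenario) adds
  ~±2 points to power estimates across seeds; cells from different seeds are
  not expected to agree more tightly than that.
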