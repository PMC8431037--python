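# Methods

This note documents the statistical choices behind `hsequity`: the models,
the defaults, the conventions adopted where the literature leaves room, and
the limits of what the synthetic-data tests demonstrate.

## Study design being emulated

The package targets a two-group comparative design: person-level survey
records nested in communities nested in cities, a binary *group* label
(in-county vs across-county migration under county-pooled insurance), two
binary utilization outcomes (clinic visit in the past two weeks; hospital
admission in the past 12 months), and categorical covariates. Group
membership is self-selected, so the analysis chain is: remove compositional
bias by matching, quantify clustering with variance components, decompose
the remaining gap, and split it into need-driven and inequitable parts.

## Synthetic cohorts

`simulate_cohort` draws, in order: covariates (independent categorical
marginals by default, or a user-supplied joint sampler when
covariate dependence matters), group labels from a selection logit,
city and community random intercepts, and outcomes from
`Bernoulli(logit⁻¹(x'β_group + ν_city + μ_community))`. A single master seed
is split into one `numpy` `SeedSequence` child per stage, so any table is
bit-reproducible and stages can be varied independently.

Defaults are chosen to emulate the survey conditions the design comes from:

* 55 cities × 4 communities × 15 workers ≈ 3300 persons, matching the
  published cohort size (3322, of which 601 across-county);
* covariate margins close to the published composition (age bands
  0.39/0.36/0.25; 57.5% men; equal income quintiles; self-assessed health
  0.688/0.252/0.060 good/fair/poor);
* selection coefficients that make across-county workers younger, richer
  and slightly more often female (overall across share ≈ 0.17), the bias
  pattern matching is meant to remove;
* variance components 0.396 (city) and 0.109 (community) on the latent
  logit scale — the published null-model estimates for the in-county
  outpatient model;
* group-specific outcome coefficients loosely following the published
  odds-ratio table with extreme values damped; the across-county intercepts
  (−3.42 outpatient, −2.42 inpatient) are calibrated so the matched
  weighted gaps are small and negative (≈ −0.004 and ≈ −0.007), the regime
  of the published totals.

What the generator does **not** emulate: survey sampling weights and
nonresponse, the construction of city/community context indices from
yearbook sources (context covariates can simply be supplied as numeric
columns), item missingness, and any spatial or serial correlation beyond
the two nested random intercepts. Passing tests therefore demonstrate
correctness of the estimators under the stated generating process, not
robustness to those real-data complications.

## Coarsened exact matching

Records agreeing on every coarsened matching covariate share a stratum;
strata lacking either group are dropped (weight 0). Numeric cut-points
`(c1…ck)` produce half-open bins `[c_i, c_{i+1})`, so age 36 falls in the
36–50 band, matching the usual age-band labels.

Two weight conventions circulate under the name "CEM weights":

* the **stratum-ratio weights** stored in `MatchResult.cem_weight` —
  treated (across-county) records weight 1, comparison records
  `(m_s^u/m_s^r)·(M^r/M^u)` — which preserve the comparison group's total
  at `M^r` (the Stata `cem` convention);
* the **equalized weights** from `MatchResult.equalized_weights`, the same
  weights rescaled so both groups' weighted totals equal the matched
  treated size (the "equalize the numbers of the two groups" phrasing).

The two differ only by one global factor on the comparison group, so every
scale-invariant diagnostic (L1, balance percentages, chi-square on
proportions, weighted group means) is identical under either.

L1 imbalance is computed over the same coarsening used for matching by
default (a separate diagnostic binning may be passed); empty cells
contribute `|0−0| = 0`. Balance tests are Pearson chi-square applied to
weight-scaled (effective) counts — a pragmatic convention for "weights
considered" tests; it is exact for unit weights and approximate otherwise.
A single-level covariate yields a NaN p-value rather than an error.

## Multilevel logistic models and ICC

The three-level random-intercept logit is fitted by maximum likelihood with
a Laplace approximation, written in the spherical parametrization
`η = Xβ + σ_city·A_c z_c + σ_comm·A_m z_m`, `z ~ N(0, I)`:

1. an inner Newton solver finds the latent-effect mode, exploiting the
   nested sparsity — the penalized Hessian is block diagonal with one
   (1 + communities) block per city, solved in closed form by a Schur
   complement, so each iteration is O(n);
2. a cheap profiled pre-search (β solved jointly with the mode, the
   `glmer nAGQ=0` scheme) locates the variance parameters;
3. the full Laplace objective — penalized log-likelihood at the mode minus
   half the log-determinant of the latent-block Hessian — is then maximized
   over (β, σ_city, σ_comm) jointly with bounded L-BFGS, which removes the
   attenuation the profiled scheme induces on the fixed effects. On
   simulated three-level data the result agrees with `lme4::glmer`
   (`nAGQ=1`) to ~10⁻³ in coefficients, variance components and
   log-likelihood (an automated cross-check in the test suite).

σ = 0 is an interior point of the spherical parametrization, so boundary
estimates need no special casing; fitted variances below 10⁻⁸ are reported
as exactly 0 (published tables print values like 5 × 10⁻³³, which are
boundary estimates in this sense). Wald standard errors come from the
numerical observed information of the Laplace log-likelihood over fixed
effects and (non-boundary) standard deviations jointly, so
variance-parameter uncertainty propagates into them. Possible separation is
reported as non-convergence with a message (a fixed effect beyond ±15 on
the logit scale, or a stalled Newton), never silently. With both variances
pinned at zero the inner Newton *is* exact ML for the plain logit and
reproduces `statsmodels` GLM to ≤10⁻⁶.

CEM (or other) weights multiply each observation's log-likelihood
contribution. **Limitation**: this is weighted pseudo-likelihood; when
weights vary *within* clusters the variance components can be badly biased
(on a simulated matched cohort the community variance inflates several-fold
— `lme4` with the same weights behaves identically). Unweighted fits
recover the generating variances. Weighted variance components should be
read as descriptive of the weighted pseudo-population, not as estimates of
the generating variances.

The intraclass correlation uses the latent-threshold convention for the
logit family: level-1 variance fixed at π²/3, so

```
ICC_city       = σ²_city / (σ²_city + σ²_community + π²/3)
ICC_community  = (σ²_city + σ²_community) / (σ²_city + σ²_community + π²/3)
```

The community-level ICC is *cumulative* (city + community share): that is
the only reading under which the worked examples (0.396, 0.109 → 0.104 and
0.133) are mutually consistent. For the gaussian family the estimated
residual variance replaces π²/3. The decision rule `needs_multilevel` uses
a strict inequality at the conventional threshold 0.059.

The gaussian (identity-link) case of the same nesting is delegated to
`statsmodels` MixedLM (city as grouping factor, community as a variance
component); it exists as the special case of the model family and is not
exercised further.

## Fairlie decomposition

Coefficients come from a weighted ML logit on the pooled two-group sample —
the plain pooled model, without a group-membership indicator, which is the
original convention (the indicator variant is available via
`include_group_indicator=True`; its coefficient is excluded from the
decomposition either way).

For the characteristic (explained) effect: the larger group is subsampled
to the smaller group's size — sampling without replacement with probability
proportional to CEM weight — both samples are ranked by predicted
probability (ties broken by a seeded shuffle) and paired by rank, and each
covariate block (all dummies of one covariate together) is switched from
the u-values to the paired r-values, one block at a time. The change in
mean predicted probability at the switch is that block's contribution for
that ordering; contributions are averaged over `n_orderings` random
orderings (default 100, the conventional figure) per subsample draw, and
over `n_subsample_draws` draws (default 100; with equal group sizes the
subsample step is the identity and a single draw is used).

By the telescoping of switches, the block contributions of a single
ordering sum exactly to the characteristic bracket on the paired samples;
`explained` is defined as that sum and `unexplained = total_gap − explained`,
so the decomposition identity holds to machine precision regardless of the
Monte-Carlo settings. Contribution Monte-Carlo standard errors are
clustered at the draw level (orderings within one draw share a pairing and
are not independent). Signs follow the u − r (across minus in) convention,
and contributions are on the probability scale; the percent columns in the
exports are explicitly labelled to avoid the probability-vs-percent
ambiguity that decomposition tables often suffer from.

Covariates in the pooled model but not listed as blocks are left at the
u-values throughout, so their compositional differences land in the
unexplained term.

## Need vs inequity

The default need partition is {age group, gender, self-assessed health} —
the demographic/health-status covariates whose contribution to a
utilization gap is considered legitimate; it is configurable, and the sum
of contributions plus the inequity index reproduces the total gap by
construction on both the probability and the percent scale. The partition
is a normative choice, not a statistical estimate.

## Pipeline and determinism

`run_pipeline` chains the stages on one cohort (simulated or read from
CSV), writes every table as CSV plus a JSON manifest of all settings, logs
each stage to stderr and `pipeline.log`, and aborts with the failing stage
name while keeping earlier outputs. All randomness flows from the config
seed through `SeedSequence` splits, so a rerun with the same config is
byte-identical (the log file carries timestamps; the tables do not).

## Problem sizes used in the test suite

Unit tests run on cohorts of a few hundred records. The parameter-recovery
study uses 50 replicates of 200 cities × 5 communities × 30 workers
(30 000 records each) with σ² = (0.4, 0.1) — cluster counts large enough
that Laplace bias is negligible relative to sampling error — and checks
95% Wald-interval coverage per coefficient (threshold 90% of seeds) and
mean latent-scale ICCs within ±0.03 of the variance-formula values. The
decomposition identity and CEM balance properties are each checked on 100
randomly parametrized small cohorts; the decomposition is also checked
against a brute-force enumeration over all rank-pairings at n = 6 and a
closed form at n = 20 per group.

## Known limitations

* Weighted variance components are pseudo-ML (see above).
* No random slopes, no probit family, no standard errors for decomposition
  contributions, no concentration-index inequity framework — all outside
  this package's design.
* The chi-square on effective counts is approximate under non-unit weights.
* The published tables this design mirrors contain two internal
  inconsistencies (mutually contradictory inpatient variance components in
  the text, and mixed coefficient/odds-ratio columns in the adjusted-model
  table); where they matter, the values consistent with the reproducible
  ICC arithmetic (city 0.294, community ≈ 0 → ICC 0.082) were adopted.
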