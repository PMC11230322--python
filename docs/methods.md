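# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic-data tests do and do not establish.

## Index construction

Food-group intakes (servings/day) are summed from item-level columns
where an item map is configured (the potatoes group is fed by four
predominantly-potato items: white potato, French fries, salty snacks,
low-fat salty snacks) and otherwise taken as direct group columns.
Within each gender stratum, each group's intake is cut at the
20/40/60/80th empirical percentiles (linear interpolation) and scored
1–5; reverse-coded groups receive `6 − s`.  The raw index (sum over
`G` active groups, range `[G, 5G]`) is rescaled by `18/G`, the unique
linear map through the origin sending `[G, 5G]` onto `[18, 90]`; with
all 18 groups the raw and rescaled indices coincide.

**Tie rule.**  A value equal to a cutpoint falls into the lower bin,
and duplicated cutpoints (which arise under heavy zero inflation)
collapse bins so that affected participants take the lowest applicable
score.  The rule is deterministic and is applied identically to the
quintile scores, the decile bins of the index, and the quintile
covariates.  Decile bins carry their median index value, used as the
exposure for the trend test.

**Stratification.**  Quintiles, deciles and the quintile covariates are
computed within gender by default (mirroring sex-specific source
cohorts); a whole-cohort option exists (`stratum=None` /
`stratify_quantiles=False`).  Strata below a configurable minimum size
(default 20) are rejected rather than silently scored.

## Survival model

Cox proportional hazards with age as the time scale: entry age is the
left-truncation time, exit age the event/censoring time.  Fitting is
delegated to lifelines' `CoxPHFitter` (Efron tie handling, its
default); the package owns the exposure designs, the per-10-unit and
extreme-decile summaries, the trend test and the meta-analysis.  CIs
are Wald intervals on the log-HR scale (±1.96 SE), p-values two-sided
Wald tests, significance nominally at 0.05.  Robust (sandwich)
variances are available via `fit_cox(..., robust=True)` but are off by
default.  Gender-stratified estimates are pooled by fixed-effects
inverse-variance meta-analysis; the combined stratum exists only
through that pooling.  Non-converged fits are returned flagged
(`converged=False`), excluded from multiverse summaries together with
their paired partner, and counted — silent dropping would bias the
distributional comparisons invisibly.

Adjustment covariates (multivitamin use, family history of MI,
margarine and energy quintiles, diabetes, hypercholesterolemia,
hypertension, smoking, physical activity, alcohol, aspirin, BMI
category, race, region, plus hormone use and past oral-contraceptive
use in the female stratum) are entered as numeric codes, with
multi-level categories treated linearly.  Since the generator draws
covariates independently of diet by default, this coding choice does
not affect the exposure estimates materially; it keeps the ~16-term
fits fast enough for 4,096-model sweeps.  Covariates constant within a
stratum are dropped from that stratum's design.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not any
particular participant:

* **Intakes** — zero-inflated log-normal per group (a Gaussian copula
  correlates both the zero state and the positive magnitude between the
  two captures, default correlation 0.6), reproducing the heavy ties at
  zero that stress quantile binning.
* **Two captures** — the second capture exists for 60% of participants;
  exposure resolution averages the captures, uses capture 1 alone when
  type 2 diabetes preceded capture 2, and carries capture 1 forward
  when capture 2 is missing.  The resolved value therefore never leaves
  the convex hull of the captures.
* **Eligibility** — prior-disease flag, sex-specific energy bounds on
  baseline intake (women <600 or >3,500 kcal/day; men <800 or >4,200),
  and covariate completeness (female-only covariates checked only for
  women); applied sequentially with a per-rule exclusion log; the
  filter is idempotent.
* **Events** — inverse-transform sampling from a Weibull-baseline
  proportional-hazards model on the age scale, conditional on survival
  to the entry age, with the linear predictor `Σ β_g · x_g` over
  *resolved* group intakes.  Censoring at `entry + Uniform(12, 17)`
  years (the administrative end of follow-up for a 2003–2007 enrolment
  window observed through 2019) capped at age 100.  The closed-form
  conditional survival function serves as the oracle in the tests.

Defaults are calibrated a priori to the headline structure of the
target cohort: 13,684 participants, ~58% female, entry ages
truncnorm(64, 9) on [45, 90], and Weibull(shape 5, scale 126), which
yields ≈6.3% incident events (≈868 of 13,684) over the follow-up
window.  Eligibility then trims ~9%, so the simulated analytic sample
is slightly smaller than its real counterpart.  Not modelled: competing
mortality and dropout (so simulated person-time is longer than a real
cohort's at the same event count), the 110-item FFQ instrument,
regional/racial sampling design, and diet–covariate confounding
(available as effects through `group_log_hazard_effects`; covariates
are independent of diet by default so that parameter recovery is
interpretable).  Passing tests therefore demonstrate the pipeline's
internal correctness and calibration under the assumed data-generating
model, not robustness to misreporting, confounding or informative
censoring in real data.

### Known-effect recovery scenario

`protective_scenario_params()` makes whole grains protective at
log-hazard −0.5 per serving/day (HR 0.61/serving) and lowers the
baseline scale to 93 so that ≈300 of 2,000 participants have an event
*net of the protective effect*.  The effect size was calibrated by
simulation: quintile scoring plus summation over 18 groups dilutes a
single group's per-serving effect by roughly a factor of 20 on the
per-index-unit scale (the regression of one group's score on the index
is ≈ Var(s)/Var(index) = 2/36), so a weak generating effect would
leave the sign of the fitted index-level HR near a coin flip even when
the group-level effect is easily detected.  At the calibrated settings
the direction is recovered in essentially every replicate (the
acceptance test requires ≥90% of 20).

## Multiverse mechanics

Quintile scores are cached per unique group composition (a group's
score depends only on its own summed intake distribution and the
stratification), so the 4,096-coding enumeration scores the 18 groups
once.  Enumeration order is lexicographic over the plant groups in
their canonical order, labels are the direction bit-vectors, and the
family is closed under the all-plants flip — which is why the
hPDI-oriented and uPDI-oriented families coincide as sets and only one
orientation needs to be reported.  The scaled 2⁶ = 64-coding
configuration (first 3 healthy + first 3 unhealthy plant groups, all 6
animal groups) is used in the test suite and acceptance script to keep
run times in minutes; the full 4,096-model run is exposed through the
CLI as a long job.

**Empirical 95% spread** of a specification family is reported as the
2.5th–97.5th percentiles of the HR distribution (a percentile choice;
mean ± 1.96 SD would be the alternative reading).  The paired t-test
uses the single-bit-flip pairing, giving `2^(P−1)` pairs and
`2^(P−1) − 1` degrees of freedom; pairs containing a non-converged fit
are dropped together and counted.

## Reporting

Tables (volcano, distribution, ECDF, decile medians, group summaries,
manifest) are the contract; plots are a separable convenience layer.
Exports use fixed file names, canonical row ordering and a fixed
10-significant-digit float format, so identical inputs produce
byte-identical files.

## Problem sizes

The shipped test suite and acceptance script use cohorts of 500–2,000
participants, 20 replicates for the recovery scenario, 200 replicates
at n = 1,000 for null p-value calibration, and the 64-coding scaled
agnostic enumeration; one full-size (n = 13,684) null cohort is
generated in the acceptance script to report its event count and null
index HR.  These sizes were chosen so a complete run finishes in
minutes on a single core while keeping Monte-Carlo error well inside
the asserted tolerances (3 SE bands; KS at the 1% level).
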