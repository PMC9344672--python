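# Methods

This note documents the statistical procedures implemented in `pmrelapse`,
the assumptions behind the synthetic cohort generator, the numerical choices
made where the design was genuinely open, and what the test suite does and
does not demonstrate about behaviour on real data.

## Data model and eligibility

The unit of analysis is the outpatient visit. Two tables carry the cohort:
a per-patient baseline table (covariates measured before glucocorticoid
treatment started, plus the follow-up window) and a per-visit table (date,
prescribed oral prednisolone dose in mg/day, the clinician/patient
judgement fields, and the treatment-change fields). Dates are calendar
dates; all analyses convert to days since baseline (0-based). One year is
365.25 days throughout.

A visit can contribute a relapse only when all of the following hold:

* strictly more than 30 days after treatment start (an initial-response
  period during which no relapse is counted);
* prescribed dose strictly above 2.5 mg/day (low-dose visits are excluded
  because dose maintenance at that level often reflects concomitant
  disease rather than PMR activity);
* at most 90 days after oral prednisolone treatment ended (day 90 itself
  is still included; day 91 is out);
* within the patient's follow-up window.

"Treatment ended" is operationalised as the first zero-dose visit with no
later positive dose, the minimal definition derivable from dose records —
a restart therefore cancels a provisional treatment end. When several
exclusion rules apply to one visit a single reason is reported, with
precedence `after_followup_end > post_treatment_window > too_early >
dose_at_or_below_2_5`.

## Relapse criteria and debouncing

Two criteria are applied to each patient's eligible visit stream:

* **RJ** (rheumatologist judgement): not in remission at the visit, or a
  relapse reported between visits (by clinician and/or patient);
* **TI** (treatment intensification): a prednisolone dose increase between
  visits or advice to increase, a DMARD started or increased for
  inefficacy, or a local/intramuscular glucocorticoid injection added.

Between-visit observations (RJ clause b, TI dose changes) are attributed to
the later visit, where a retrospective chart records them. The raw clause
only becomes a counted relapse when the *previous* visit showed no relapse
under the same criterion ("debouncing"). Two design points were open and
are both implemented, with the defaults documented here:

* **Which previous visit?** Default: the previous *eligible* visit
  (ineligible visits are outside the relapse universe). The alternative —
  the previous calendar visit — is available via `previous="any"`.
* **Raw or debounced previous state?** Default: the raw clause state
  (`debounce_on="raw"`). This reads "no relapse at the previous visit" as
  the state observed at that visit and prevents one long uninterrupted
  episode from re-triggering on alternate visits. The alternative
  (`debounce_on="flag"`), which compares with the previous debounced flag
  and does re-trigger on alternates, is implemented and tested.

Debouncing implies no two consecutive eligible visits of a patient are both
counted, so a patient's event count is at most half their eligible visits
(rounded up).

## Agreement

Visit-level agreement cross-classifies the RJ and TI flags over all
eligible visits. With observed agreement P₀ and chance agreement
Pₑ = p_A·p_B + (1−p_A)(1−p_B) from the marginal positive rates, Cohen's
κ = (P₀ − Pₑ)/(1 − Pₑ). Because relapses are rare at visit level, Pₑ is
dominated by its double-negative term (reported separately as
`pe_negative_cell`), which is how ~87% raw agreement can coexist with
moderate κ. `kappa_from_marginals` inverts a published summary (total,
marginal positives, P₀) back to Pₑ, the double-negative cell and κ, after
checking the implied double-positive cell is feasible.

Patient-level agreement classifies each patient by ≥1 relapse within a
horizon (1 or 2 years), with all patients in the denominator.

Intervals: Wilson score for P₀; for κ the large-sample standard error of
Fleiss, Cohen & Everitt (1969) with a normal approximation, truncated at 1.
Neither method is canonical for this design; these are the standard
choices, and the κ computation (point estimate and interval) is
cross-checked against `statsmodels.stats.inter_rater.cohens_kappa` in the
test suite.

## Incidence

* **Cumulative incidence** at horizon h = proportion of patients with ≥1
  relapse within h·365.25 days of baseline. Default denominator: every
  patient in the analysis set, regardless of individual follow-up length —
  this matches how registry summaries are usually printed but can
  understate incidence when follow-up is short; an `at_risk` denominator
  (patients whose own follow-up reaches the horizon) is provided.
* **Incidence rate** = total events / total person-years. Person-time runs
  from baseline to the end of the eligible-visit window: follow-up end
  capped at treatment end + 90 days (computed from dose records when the
  visits table is supplied). A last-visit censoring rule is available
  (`rule="last_visit"`); which convention a published total used is often
  unknowable, so both are explicit.

## Univariable screening

Twelve baseline candidate predictors: age, sex, history of cardiovascular
disease, history of malignancy, smoking (never/stopped/current, never as
reference), pre-treatment symptom duration, the 0–8 clinical severity sum
score, peripheral arthritis, systemic symptoms, CRP, ESR and haemoglobin.
CRP and ESR enter divided by 10 (per 10 mg/L / per 10 mm/h) for coefficient
interpretability. Symptom duration is recorded in weeks; it enters the
models in months (weeks/4.345) by default because that is the conventional
reporting unit, with a weeks option since source reports mix the two.

Each predictor is fit alone against three outcomes: relapse within 1 year
and within 2 years (maximum-likelihood logistic regression, odds ratios)
and relapses per patient-year (Poisson regression of per-patient counts
with a log person-time offset, incidence rate ratios). Fits are
complete-case per predictor (multiple imputation is reserved for the
multivariable model); Wald 95% intervals and p-values; significance flagged
at p < 0.05. Degenerate outcomes raise explicit errors and perfect
separation is detected and raised rather than silently returning a huge
estimate; in the full screening table a failed cell is marked and the rest
of the table survives. The smoking factor contributes two dummy contrasts,
so the default table has 13 rows. GLM fitting is statsmodels throughout.

## Multiple imputation

Missingness in routine PMR records concentrates in smoking, symptom
duration, CRP, ESR and haemoglobin. `MultipleImputer` runs chained
equations over the incomplete variables with all other candidate
predictors and the analysis outcome in every conditional model:

* continuous variables: Bayesian linear regression (residual variance drawn
  from its scaled inverse-χ², coefficients from their normal posterior)
  followed by **predictive-mean matching** with a 5-donor pool, so imputed
  values always lie in the observed support;
* categorical variables: multinomial logistic regression (standardised
  inputs, moderate ridge for numerical stability), category drawn from the
  predicted probabilities.

Defaults: m = 20 completed datasets, 10 cycles each, seed-deterministic.
Observed cells are never altered; a fully observed input returns m
identical copies, which makes Rubin pooling collapse exactly to a single
fit (between-imputation variance zero) — a tested identity.

## Prediction model development and validation

Outcome: TI relapse within the first treatment year (binary). Candidate
set: the 12 baseline predictors; a warning (not an error) is raised when
candidates exceed events/10, the usual events-per-variable heuristic.

1. Within each completed dataset, backward elimination from the full
   candidate set: refit, drop the variable with the largest Wald p-value
   (χ² over a dummy group, so a factor leaves as a block), stop when all
   remaining p ≤ 0.157 — the AIC-equivalent retention threshold commonly
   used with this recipe.
2. Across imputation sets, keep variables retained in **more than 50%** of
   sets; per-variable inclusion fractions are always reported so the
   stability of the selection is checkable, not just asserted. A variable
   retained in, say, 40% of sets is dropped.
3. Refit the kept variables on every completed dataset and pool by Rubin's
   rules: pooled coefficient = mean; total variance = within +
   (1 + 1/m)·between. If nothing survives selection the model degrades to
   intercept-only with a warning.
4. Apparent discrimination = c-statistic (AUC) of the pooled linear
   predictor, computed per imputation set and averaged, reported with the
   across-set range.
5. Internal validation by the Harrell bootstrap: resample patients with
   replacement, re-run the *entire* procedure (imputation, selection,
   pooling) on the resample, and record the excess of the bootstrap
   model's AUC on its own sample over its AUC on the original data.
   Optimism = mean excess over resamples (default 500; 100 minimum);
   corrected AUC = apparent − optimism. Resamples with a constant outcome
   are redrawn up to 10 times, then skipped with a warning.

`predict_proba` applies the inverse-logit of the pooled linear predictor
and requires observed (or externally imputed) values of the selected
covariates. A sensitivity analysis on the subset of patients meeting the
2012 EULAR/ACR core classification criteria reruns the identical pipeline
via `sensitivity_subset`.

## The synthetic cohort generator

The generator emulates the structure of a single-centre retrospective PMR
cohort so that every pipeline stage can be tested with known truth.

**Baseline covariates** are drawn independently: age N(66.4, 8.8); 55.9%
female; cardiovascular history 14.1%; malignancy 12.2%; smoking
never/stopped/current at 47.2/20.9/12.5% (the remaining share is the
smoking missingness); symptom duration gamma with mean 14 and SD 13.7 weeks
(moment-matched, keeping it positive and right-skewed); CRP and ESR
log-normal matched to medians/IQRs of 29 (15–52.5) mg/L and 37 (26–51) mm/h
(σ = ln(q₃/q₁)/(2·0.6745)); haemoglobin N(8.2, 0.741) mmol/L; the 0–8
severity score distributed as the convolution of the four independent
0/1/2 girdle items at their observed marginals; arthritis 15.3%; systemic
symptoms 43.6%; EULAR/ACR core criteria met by 79% (a Bernoulli draw — the
criteria are not reconstructed from the drawn covariates).

**Visits and taper.** Visits occur every 42 days ± 7 (uniform jitter), one
taper step per uneventful visit along
15 → 12.5 → 10 → 8.75 → 7.5 → 6.25 → 5 → 3.75 → 2.5 → 0 mg/day. The ~6-week
step spacing and this dose ladder are a reconstruction of guideline-based
tapering, not an observed protocol. Follow-up ends at `followup_max`
(default 5 years) or once 90 days have passed after the dose reached zero.

**Relapse process.** True relapses arrive as a Poisson process with
per-patient rate exp(intercept + Σβ·x) per patient-year (covariates centred
at their configured reference values, so the intercept is the reference
patient's rate; default intercept log 0.35). Events are drawn per
inter-visit gap and recorded at the closing visit as a treatment
intensification: 80% a dose step-up (back one taper step), 10% a DMARD
start/increase, 10% a GC injection. At doses at or below 2.5 mg/day —
including after treatment stopped — the recorded action is always a dose
step-up to the lowest taper step above 2.5 mg/day, since intensifying a
DMARD while leaving near-zero prednisolone untouched is clinically
implausible; this also means a recorded relapse is always attached to an
eligible visit. A step-up resets any provisional treatment end.

**Judgement noise.** RJ fields are the TI state corrupted per visit:
P(RJ+|TI action) = 0.63 and P(RJ+|no action) = 0.09 by default, split
70/30 between the "not in remission" and "between-visit report" clauses.
These defaults are the conditional probabilities implied by a reference
cross-classification of 2422 visits with 399/321 positives at 87%
agreement; at that visit density they reproduce κ ≈ 0.49. Note that κ
depends on the criterion-positivity per visit: under the generator's
default 6-weekly schedule the TI positivity per eligible visit is lower
(~0.07 rather than ~0.13), so the same noise yields visit-level κ ≈
0.31–0.42 on synthetic data. This is a property of visit density, not of
the agreement code, and no correctness check depends on the simulated κ.

**Missingness** is injected after the event process (hazards use the
complete covariates): MCAR by default at rates smoking 19%, symptom
duration 1%, CRP 13%, ESR 5%, Hb 24%; a MAR option makes missingness
increase with age (logistic in centred age, slope 0.05/year) for
imputation stress tests.

**Determinism.** A fixed config (including its seed) yields bit-identical
tables.

**What the generator does not emulate.** Covariates are drawn
independently (no CRP–ESR correlation); the EULAR/ACR flag is independent
of the drawn covariates; visit spacing is a reconstruction, so total visit
counts and person-time differ from any real cohort (mean synthetic
follow-up is ~1.4–1.6 years under the default single-pass taper, against
~2.2 years in the reference cohort, whose tapering was evidently slower);
relapse hazards are time-constant per patient; there is no giant cell
arteritis co-occurrence, comorbidity flares, or GC adverse events; and
recording is perfect apart from the configured judgement noise. Passing
tests therefore demonstrate the *statistical machinery* — rules, estimators,
selection, pooling, optimism correction — not that real PMR data satisfy
these models.

## Numerical choices and test design

* **Discretisation of the event process.** Recording relapses at the next
  visit merges multiple events in one gap and debouncing suppresses an
  event directly following a recorded one, so the naive incidence-rate
  estimator is attenuated by roughly a factor (1 − λΔ) plus an end-of-
  follow-up tail — about 7–9% at λ = 0.35/year with 42-day visits. The
  rate-recovery tests therefore compare the adjudicated count against the
  *exact expectation* of the debounced per-gap recording process computed
  from the realized gaps, E = p₁ + Σᵢ pᵢ(1−pᵢ₋₁) with pᵢ = 1−exp(−λgᵢ),
  using a test configuration (all doses above 2.5 mg/day within a 2-year
  window) in which every post-baseline visit is eligible and gaps are
  independent of events, the regime where that expectation is exact.
* **Separation.** Perfect separation raises an explicit error (statsmodels
  separation diagnostics plus a diverging-coefficient check) instead of
  returning an astronomically large OR.
* **PMM ties** are broken by a uniform draw among the k nearest donors;
  linear systems carry a 1e-8 ridge for conditioning.
* **Problem sizes in the suite** were chosen to make the checks sharp at
  desk scale: constant-hazard recovery uses n = 2000 patients × 100
  replicates at λ = 0.35 (plus 10 replicates each at 0.1 and 0.7);
  regression calibration uses 500 null replicates (type-I error within
  5% ± 2%) and 100 coverage replicates at n = 5000; the null-discrimination
  check uses n = 1000 with 200 bootstrap resamples; coefficient-recovery
  style checks run at reduced m and replicate counts. All seeds are fixed.

## Known limitations

* The across-imputation selection recipe (backward elimination per set at
  p < 0.157, then majority inclusion) is one standard recipe among
  several; stacked selection or group-lasso alternatives are not
  implemented.
* The κ interval uses the asymptotic SE; exact or bootstrap intervals are
  not provided.
* `predict_proba` does not impute: scoring an incomplete new record
  requires imputing it first (by design, to keep scoring deterministic).
* Visit-level κ on synthetic data depends on the configured visit density
  (see above) and should not be read as a reproduction of any particular
  cohort's κ.
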