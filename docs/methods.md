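# Methods

This note documents the models, rules and numerical choices implemented in
`uti_episodes`, in the package's own terms: what each stage computes, which
parameters matter, what the synthetic-data generator does and does not
emulate, and where design decisions were genuinely open.

## Study design being modelled

The pipeline reproduces the design of a retrospective cohort study in linked
English primary-care, hospital and death-registration data: adults aged ≥65
consulting primary care for suspected community-onset lower UTI, compared by
whether a systemic antibiotic was prescribed on the day of consultation
(immediate) or not (delayed by 1–7 days or withheld, analysed as a single
not-immediate group, since delayed prescribing is poorly recorded in EHRs).
The primary outcome is coded-sepsis evidence — interpreted as bloodstream
infection (BSI) — within 60 days of the episode start; secondary outcomes
are 60-day all-cause death and hospitalisation unrelated to UTI or BSI.
Confounding by indication is the central inferential threat: prescribers
treat sicker or more accessible patients differently, so treatment groups
differ systematically at baseline.

## Cohort intervals

Entry is the latest of the practice's up-to-standard date, registration
start + 365 days (plain calendar arithmetic — leap-day handling would move
entry by at most one day), the 65th birthday, and the study start
(2007-04-01 by default). Exit is the death date for patients who die, else
60 days before the earliest of last collection, transfer-out and study end —
the buffer guarantees every analyzed episode has complete 60-day follow-up,
while patients who die within the buffer are retained because removing them
would select against the outcome pathway that matters for the mortality
endpoints. Person-years use 365.25-day years.

## Episode segmentation

All UTI-coded dates of a patient (primary-care events and hospital
diagnoses, deduplicated within day) are scanned in order with two state
variables, the current episode start and the date of last evidence:

- a code within 60 days (inclusive) of the current start joins the episode;
- a code more than 60 days after the start *and* more than 60 days after
  the last evidence opens a new episode;
- otherwise the code is an *ongoing* episode: excluded from analysis but
  still refreshing the last-evidence marker, so it keeps blocking new
  episode starts until a clear 60-day gap.

Because every code — member, ongoing or start — refreshes the last-evidence
marker, "last evidence" always equals the previous code date; the test
suite exploits this to check the state machine against an independent
two-comparison-per-date classifier on random instances.

Episodes are then filtered to community onset, in fixed precedence order so
each exclusion carries exactly one reason: (1) any same-day hospital
admission, A&E attendance, specialist referral or death (precedence in that
order); (2) start date inside any hospital spell, discharge day inclusive —
this also disposes of hospital-onset UTI, whose codes may still open
episodes for blocking purposes; (3) start outside the patient's at-risk
interval. The 30-day sensitivity variant reruns the same machine with a
30-day window everywhere (segmentation and outcome windows).

## Analysis rows

Covariates use history strictly before the episode start; utilisation
windows (prior 7/30/365 days) end the day before the start so the index-day
prescription, which defines the exposure, cannot leak into the
prior-antibiotic covariate. Outcome windows include day 0; because same-day
admissions, attendances and deaths are excluded upstream, only a same-day
primary-care sepsis code can produce a day-0 BSI. Specific rules:

- **Charlson comorbidity index**: weighted sum over the classic 17 groups
  ever coded before the start (weights shipped with the synthetic
  codelist). Days in hospital in the prior year are counted as the length
  of each spell's intersection with the window (admission-to-discharge
  difference, so a same-day admission contributes zero days).
- **Smoking**: latest code before start wins; a latest "non-smoker" with
  any earlier smoking record is reclassified as ex-smoker; no codes means
  non-smoker.
- **Recurrent UTI**: an explicit recurrent-UTI code any time before start,
  a nitrofurantoin/trimethoprim prescription of ≥28 days any time before
  start (prophylaxis), or ≥2 primary-care UTI consultation dates in the
  prior year. Consultation dates, not episodes, are counted; the
  alternative reading is not distinguishable from the source design.
- **BSI source**: if any hospital spell admitted in the outcome window
  carries a sepsis diagnosis, the episode is hospital-confirmed and
  classified by the hierarchy urosepsis > other-infectious (with a
  lower-respiratory subflag) > unspecified, plus a flag for the sepsis code
  holding diagnosis position 1 ("primary reason for admission"). Otherwise
  the episode is primary-care-only, subclassified by what the hospital
  record in the window shows: a UTI code, another infection, a
  non-infective admission, or no admission at all.
- **Financial year**: April-1 boundary (UK NHS convention).
- Rows missing IMD quintile or region are dropped at this stage and
  counted in the table's `attrs`.

Count covariates (CCI, admissions, hospital days, A&E attendances) enter
all models as square roots, which tames their right skew.

## Estimation

Marginal logistic models are fitted by GEE with an exchangeable working
correlation over patients (repeated episodes per patient) and Huber–White
sandwich standard errors; all CIs are Wald with ±1.96. Convergence uses a
1e-8 coefficient-change tolerance and 100 iterations; a non-converged fit
is refitted under an independence working correlation and flagged, never
silently retried. With all cluster sizes equal to one, the exchangeable GEE
collapses to ordinary logistic regression (asserted to 1e-4 in tests).

The final model keeps the exposure unconditionally and every candidate
covariate with univariable p < 0.2; multi-level categoricals are screened
by the joint robust Wald test across their indicators (per-indicator
screening is the undocumented alternative). Screening fits use a relaxed
tolerance (1e-6, 30 iterations) because univariable p-values are stable to
~1e-12 long before the final-model tolerance. A discrete candidate with a
zero outcome cell in some level is inestimable by maximum likelihood (its
coefficient diverges) and is excluded by the screen; this only binds at
simulation sample sizes, not at the population scale the design targets.

Interactions add an exposure-by-modifier product term (female indicator, or
continuous age per 5 years) and report per-stratum exposure ORs
(female/male, or 65–79/80+).

**NNEH** (number needed to be exposed — i.e., not treated immediately — to
harm): every row's outcome risk is predicted under both exposure levels
with covariates held fixed; the average risk difference (ARD) is the mean
of those per-row differences over *all* rows (marginal standardisation over
the observed covariate distribution; group-specific standardisations are
defensible alternatives and are labelled out of scope), and
NNEH = 1/ARD. Confidence intervals come from a percentile bootstrap that
resamples patients — not episodes — with replacement (200 replicates by
default), refitting the final model with its selected term set held fixed.
The NNEH interval is the reciprocal of the ARD interval; when the ARD
interval spans zero the NNEH bound is reported as unbounded, matching how
such intervals behave. An ARD within 1e-15 of zero reports an infinite
NNEH with a flag.

## Propensity-score analyses

Scores model the probability of *not* receiving an immediate prescription,
on the same covariate set as the outcome model's candidates.

- **Parametric**: logistic regression fitted by IRLS with a pseudo-inverse
  (tolerant of collinear indicator blocks); coefficients larger than 30 in
  absolute value are treated as separation and reported as an error.
- **Nonparametric**: gradient-boosted trees, depth 2, shrinkage 0.01,
  subsample 0.8, up to 800 trees; the boosting iteration is chosen to
  minimise the mean absolute standardized mean difference (SMD) under the
  implied inverse-probability weights, evaluated every 25 iterations — the
  balance-criterion stopping used by the twang tradition.

**Matching**: greedy nearest-neighbour on the logit score, without
replacement, exposed rows processed in descending score order, up to 5
controls each within a caliper of 0.2 SD of the logit score (the common
convention; the source design does not state its caliper or replacement
rule, so these are surfaced in the result metadata). Unmatched exposed rows
are counted. Balance after matching weights controls by 1/(set size), the
standard variable-ratio matching weight. Matched sets feed either the
marginal GEE of the main analysis or a conditional logistic regression
stratified on set.

**Weighting**: stabilised weights (P(exposed)/score for exposed,
P(control)/(1−score) for controls) target the average treatment effect;
weights are truncated at their 1st/99th percentiles and the truncation
count reported. The weighted analysis is a GEE with case weights, an
independence working correlation and robust standard errors.

The four-way grid (two score models × two adjustments) reports each OR with
CI, balance before/after, matched-set counts or effective sample size.

## The synthetic generator

The generator emulates the *structure* the pipeline consumes: a patient
registry with registration intervals, practice geography and deprivation;
clustered UTI consultations (gamma frailty on the per-patient rate, higher
rate in women); same-day prescribing whose probability depends on measured
covariates through a logistic assignment model (confounding by indication);
rare BSI outcomes realised as coded sepsis in hospital spells (with the
urosepsis/other/unspecified mix and diagnosis positions) or in primary care
only; deaths from a background hazard plus episode-level and post-BSI
excess; and background hospitalisations, A&E attendances, antibiotic
scripts, comorbidity, smoking and recurrent-UTI history. Every patient has
an independent random substream keyed on (seed, patient id), so enlarging a
cohort never changes existing patients' histories, and identical
(scenario, seed) pairs reproduce every table byte-for-byte.

Presets define the study conditions used throughout the tests:

- `null_effect` — exposure OR 1.0, no confounding; elevated episode and
  outcome rates over a 3-year window keep replicate studies cheap while
  leaving hundreds of events per run.
- `confounded_null` — exposure OR 1.0 with strong confounding by
  indication (home visits, recent antibiotics, gender, age, comorbidity
  acting on both assignment and outcome, directions mirroring the
  published baseline imbalances). The strengths are set so the crude OR is
  biased to roughly 2 at the replicate sizes the acceptance suite uses:
  the qualitative deconfounding property (adjusted estimates closer to the
  null than the crude) is only identifiable when the crude bias clearly
  exceeds the sampling noise of the adjusted estimators.
- `harmful_delay` — exposure OR 1.5 for BSI (1.3 for death) with mild
  confounding. This preset generates outcomes without a patient-level
  outcome frailty so the generative odds ratio coincides with the
  population-averaged contrast a marginal model estimates; with a random
  intercept the two differ by non-collapsibility and "recovering the true
  OR" would be ill-defined. Clustering still arises through repeated
  episodes and shared covariates.
- `table1_calibrated` — the full 2007–2015 window calibrated to the
  published cohort's marginals: ~87.3% immediate prescribing, ~77.5% of
  episodes in women, ~0.45% BSI per episode (0.4% vs ~0.8% by exposure
  group), ~75.7 episodes per 1,000 patient-years, ~2% 60-day deaths,
  home-visit and prior-antibiotic imbalances in the published directions.

What the generator does **not** emulate: real Read/ICD-10 code frequency
distributions (a small synthetic codelist defines the category map);
practice-level recording artefacts; HES episode-within-spell substructure;
seasonal or secular trends; free-text or microbiology. Passing tests
therefore demonstrate that the pipeline's logic and estimators behave
correctly under a faithful structural model with known truth — not that
any specific real-world estimate is reproduced, which would require the
original data.

## Numerical choices and degenerate inputs

- Dates are day-granular throughout; day arithmetic uses integer day
  offsets internally.
- Episode membership uses 0 < d − start ≤ 60 with same-day duplicates
  collapsed; the discharge day counts as in-hospital (conservative
  exclusion of hospital-onset cases).
- Ties in matching are broken by stable row order; identical scores give
  every exposed row exactly k controls in input order.
- A constant continuous variable in the descriptive table is flagged
  "degenerate" with an IQR of [c–c] and no test; chi-square tests use no
  continuity correction.
- The 2×2 odds-ratio utility refuses zero cells rather than applying a
  continuity correction.
- Percentages are rendered to 1 decimal place and ORs to 2 in formatted
  output, with full precision retained in machine-readable files.

## Problem sizes

Simulation-based checks use sizes chosen to give each property adequate
power while keeping a full test run tractable on one CPU: coverage of the
true exposure OR uses 100 replicates of 3,000 patients; deconfounding uses
100 replicates of 2,500 patients; covariate balance uses a single 10,000
patient study; segmentation is checked against its oracle on 10,000 random
instances; calibrated marginals are measured at 12,000–20,000 patients.

## Known limitations

- The delayed-prescription subgroup is generated and reported but never
  analysed separately (the comparison group pools delayed and withheld, as
  in the source design).
- The conditional-logistic matched analysis treats matched sets as
  independent even when one patient contributes episodes to several sets.
- IPW uses a weighted GEE with case weights rather than a dedicated
  survey-weighted estimator; with stabilised, truncated weights the
  difference is immaterial at the scales tested.
- The univariable screen's estimability guard (no empty outcome cells) can
  exclude sparse covariates in small simulations; at population scale it
  never binds.
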