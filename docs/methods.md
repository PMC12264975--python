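# Methods

`ttescreen` implements a high-throughput screen of prescription drugs
against all-cause mortality in a registry population, organised as one
emulated target trial per drug. This note documents the statistical
model, the design choices that were genuinely open, the synthetic-data
conditions the test suite runs under, and the known limitations.

## Case classification

A person is classified as a Parkinson-disease (PD) case from
prescriptions alone: (1) at least four fills of MAO-B inhibitors (ATC
group N04BD), or (2) at least four fills of levodopa (ATC group N04BA)
with at least one of those fills carrying the G20 reimbursement code.
The diagnosis date is the dispense date of the fourth qualifying fill;
for rule 2 the reimbursement code acts as a person-level qualifier and
does not shift the date. Incidence is enforced by removing anyone with
an antiparkinsonian (N04) fill during the prevalence-exclusion year
(default: the first coverage year). The four fills need not involve the
same substance, only the same qualifying group, and same-day duplicate
fills count separately unless collapsed by configuration — dispensing
records legitimately repeat. Classification is validated against a
diagnosis-code reference standard (two or more G20 specialist-care
records) via positive predictive value and sensitivity.

## Trial construction

For each screened drug (every ATC level-5 code outside N04 filled
post-diagnosis by at least `min_target_persons` cases, default 100):

* **Target arm** — each case's first post-diagnosis fill of the drug,
  kept if the baseline falls within five years of diagnosis, age at
  diagnosis is at least 25, and the person has no fill of the drug in
  the two-year washout before baseline (new-user condition).
* **Control arm** — initiations of drugs in the same anatomical main
  group (ATC level 1; level 2 in the stricter comparator variant) but a
  different pharmacologic subgroup (level 3). Anyone with a target-drug
  fill anywhere in the registry is excluded; the same eligibility rules
  apply with the washout on the control drug itself; control baselines
  are restricted to the calendar-year range of the retained target
  baselines; each person contributes one initiation (earliest eligible,
  ATC-lexicographic tie-break); and arms larger than 10,000 are reduced
  by a seeded uniform subsample.

All lookback windows (washout and covariates) are open at both ends: a
fill exactly at `baseline − window` or on the baseline date itself is
outside the window. Death is recorded at month resolution and imputed
to the 15th when a calendar day is needed (configurable).

The general-population variant draws a seeded sample (default 10%) of
persons aged 65+ at a fixed index date, drops all diagnosis-linked
criteria, and subsamples controls to four times the target arm.

## Covariates and balance

Baseline covariates per initiation: sex, education (missingness is its
own level, so the covariate table has no missing cells), age at
diagnosis and at initiation (fractional years from January 1 of the
birth year — only birth year is observed), calendar year of initiation,
a prescription-based comorbidity index, and binary flags for the 20 most
common comorbidity categories in the screen population (two-year
lookback).

The comorbidity index follows the RxRisk construction: drug fills map to
chronic-condition categories through ATC prefixes (first match wins in
mapping order), and the index sums the mortality-association weights of
the distinct categories present in the lookback. The nationally
calibrated weight table is not redistributable, so the package ships a
**synthetic** 46-category default mapping (level-2 prefixes, weights in
[−1, 7]) with the same structure, and accepts a user-supplied mapping
CSV. Any analysis of real data should substitute a validated mapping.

Stabilized inverse-probability-of-treatment weights come from a
main-effects logistic propensity model of arm on all one-hot-encoded
covariates (first level dropped; constant columns removed and logged),
fitted by IRLS to a relative deviance tolerance of 1e-8 (max 100
iterations) on an internally standardized design. Weights are
`P(A=a)/P(A=a|L)` with the marginal arm frequency as numerator; no
truncation by default (the maximum weight is always reported).
Balance is measured per encoded column as
`|weighted mean difference| / sqrt((v_t + v_c)/2)` with unweighted arm
variances; a column is balanced below 0.1 and the balanced fraction is
reported. Quasi-complete separation raises an error naming the
separating covariate.

## Outcome model and effect measures

Follow-up is discretized into months from baseline; month *t* covers
`[baseline + (t−1)m, baseline + t m)`. A death in month *d* contributes
rows 1..*d* with the event on the last; censoring (emigration,
administrative end of coverage, or the 96-month horizon) contributes
fully observed months only. The one-year-lag variant censors deaths in
months ≤ 12 and starts follow-up at month 13.

The hazard is modelled by weighted pooled logistic regression of the
monthly event on `{1, t, t², A, A·t, A·t²}` — a full quadratic time
trend per arm, time entering as the raw month index. Per-arm cumulative
risk uses the product-limit identity
`R_a(t) = 1 − Π_{k≤t} (1 − h_a(k))`. Because confounding is handled
entirely by the weights, per-arm risks are read directly off the
weighted model (no additional covariate standardization); in the
`adjust_unbalanced` sensitivity variant, unbalanced covariates enter the
outcome model as main effects and risks are standardized over the
weighted cohort. Effect measures at 96 months, on the per-100-person
scale: rd = control − target, rr = target/control, NNT = round(100/rd)
(half-up, reported only when rd > 0). Confounder-adjusted survival
curves use the weighted product-limit (IPTW Kaplan–Meier) estimator,
which the pooled logistic reproduces exactly under a saturated time
model — an identity the tests assert.

## Inference and the screen

Each trial's rd and rr get 95% percentile confidence intervals from a
nonparametric bootstrap (default B = 500): persons are resampled with
replacement from the pooled cohort (arm sizes vary), and both the
propensity model and the outcome model are re-estimated inside every
replicate. Resampling is implemented through multinomial multiplicity
counts so that replicates reuse precomputed design matrices; the outcome
rows are further aggregated into (month, arm, event) cells, which leaves
the weighted likelihood unchanged and makes refits cheap. The p-value
for rd uses the normal approximation `2Φ(−|rd|/sd_boot)` (the percentile
inversion p is available behind a flag; at B = 500 its granularity is
0.002, too coarse for the small p-values the screen reports). Failed
replicates — separation, non-convergence, an emptied arm, no events —
are dropped and counted; more than 10% flags the trial unreliable.

Across the screen, p-values are corrected with the Benjamini–Yekutieli
step-up procedure (valid under arbitrary dependence among the drug
trials), applied over all completed trials. A drug is a **hit** when
rd > 0, the nominal p < 0.05, and at least 90% of covariates are
balanced after weighting. Per-trial seeds derive from the master seed
and the target ATC code, so results do not depend on enumeration order.
Seven sensitivity variants re-run the pipeline with a single
modification each (outcome-model adjustment for unbalanced covariates,
ATC level-2 comparators, age < 75 at initiation, comorbidity index below
the screen-wide median with a strict inequality, a 12-month lag, age
≥ 65 at diagnosis, and the general-population cohort).

## Synthetic registry

The generator emulates the registry's statistical structure at a
configurable desk scale. Latent chronic comorbidities are drawn per
person and materialized **only** as regular fills of marker drugs mapped
to comorbidity categories, so covariate assembly sees comorbidity
through the prescription channel exactly as the analysis does on real
data. Drug initiation follows per-drug logistic models on the latent
comorbidities, age and sex (creating genuine confounding by
indication); mortality follows a discrete-time monthly logistic hazard
with per-drug log-odds effects applied from initiation onward; the PD
prescription pattern, G20 specialist-care records (with configurable
recording and noise rates), emigration and administrative censoring are
all simulated. Time runs on a whole-month grid; prescriptions are dated
the first of their month. Randomness is split into per-table streams
from one seed, so adding a drug does not perturb unrelated draws.

### Validation conditions and their problem sizes

Three fixed study conditions drive the heavy tests and the acceptance
script; sizes were chosen to make each check statistically informative
at desk scale.

* **Confounded null** (2,500 persons, 60% PD, one target with strong
  comorbidity-driven initiation, θ = 0, horizon 48 months, 200
  replicates, B = 200): the unadjusted rd is biased by several events
  per 100 while the IPTW estimate is centred at zero and its bootstrap
  CI covers zero at close to the nominal 95%.
* **Known effect** (4,000 persons, θ = −0.25 on the monthly log-odds,
  horizon 96, 100 replicates): the median estimated rr is compared with
  an exact oracle that replays the generator's covariate and initiation
  rules for 10⁶ persons and evaluates per-person risks in closed form —
  a route fully independent of the weighting/regression estimator.
* **Planted screen** (15,000 persons, 12 screened drugs across six
  anatomical groups, two with θ = −0.5, B = 100, 20 replicates): both
  planted drugs are recovered with few false positives. The larger
  population keeps per-arm sizes in the low thousands so that sampling
  noise in post-weighting SMDs does not spuriously fail the 90% balance
  requirement.

In all three conditions, initiation is **exclusive within an ATC
level-1 group** (a person initiates at most one study drug per group;
the earliest draw wins). This is deliberate: with overlapping initiation
windows and independent initiation, excluding ever-users of the target
from the control arm conditions dual users' control membership on dying
before their target initiation — a selection bias of the ever-user
exclusion itself, which we measured at roughly +2 per 100 on the null
rd. Exclusivity removes dual users so that the remaining checks isolate
confounding control. The generator can still produce overlapping use
(the default configuration does), which is the right setting for
studying that bias but not for calibration tests.

### What the synthetic data do not emulate

No real demographic structure, market shares, seasonal prescribing,
dose/duration information, treatment discontinuation, or time-varying
hazards beyond the treatment step; initiation is a one-shot draw rather
than a longitudinal process. Passing the suite shows the estimators
recover what the generating model encodes — it does not certify
performance on real registry data, where unmeasured confounding and the
ever-user selection noted above remain live concerns.

## Numerical choices

IRLS with step halving (deviance kept monotone), relative deviance
tolerance 1e-8, 100-iteration cap; a ridge of 1e-10 on the information
matrix guards numerically singular steps; separation is detected from
pinned fitted probabilities or diverging coefficients and reported with
the covariate name. The propensity design is standardized internally
(an affine reparametrization that leaves fitted probabilities
unchanged). Percentile CIs use the empirical 2.5/97.5 points. Ties in
top-comorbidity ranking break toward the lower category id; ties in
control-initiation dates break toward the lower ATC code. A cohort
whose arms contain only identical persons saturates the logistic hazard
(cell rates 0/1); such fits fail loudly rather than returning degenerate
intervals.

## Known limitations

* Effects are initiation (intention-to-treat) analogs; adherence and
  discontinuation are out of scope.
* The ever-user exclusion's selection bias under overlapping use is
  inherent to the design, not removable by weighting.
* The shipped comorbidity mapping is synthetic; real analyses must
  supply a calibrated one.
* The bootstrap treats the control subsample cap as fixed; uncertainty
  from the subsampling step itself is not propagated.
* At small arm sizes the IPTW estimator retains a mild finite-sample
  attenuation (the known-effect condition shows a median rr about 0.015
  above the oracle at arms of ~500), well inside the tolerance used but
  visible.
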