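# ttescreen

High-throughput emulated target trials on prescription registries:
screening every drug a registry population initiates for an association
with long-term mortality, one emulated trial per drug.

The package is aimed at pharmacoepidemiologists working with linked
national registry extracts (prescriptions with ATC codes and dispensing
dates, specialist-care diagnoses, vital-status data). It implements the
full analysis chain used in registry-based drug-repurposing screens for
Parkinson disease (PD), together with a synthetic registry generator
with known ground truth so that every stage is testable without access
to restricted data.

## What it computes

For each drug *d* with enough initiators, an emulated trial compares
new users of *d* (first post-diagnosis fill, two-year washout) with new
users of other drugs in the same ATC anatomical main group but a
different pharmacologic subgroup (active-comparator design). With
baseline covariates L (demographics, comorbidity index, top-20
comorbidity flags), the analysis uses:

* **stabilized IPTW** — w = P(A=a) / P(A=a | L), from a main-effects
  logistic propensity model; balance checked by standardized mean
  differences (balanced: SMD < 0.1);
* **pooled logistic regression** — monthly death indicator on
  {1, t, t², A, A·t, A·t²}, weighted by w; 96-month cumulative risk via
  the product-limit identity R_a(t) = 1 − Π_{k≤t}(1 − h_a(k));
* **effect measures** — rd = R₀ − R₁ and rr = R₁/R₀ at 96 months per
  100 persons, NNT = round(100/rd); IPTW Kaplan–Meier survival curves;
* **bootstrap inference** — person-level resampling (default B = 500)
  with weights and outcome model re-estimated per replicate; percentile
  95% CIs and a normal-approximation p-value for rd;
* **screen-wide FDR** — Benjamini–Yekutieli correction across all
  completed trials; a drug is a *hit* when rd > 0, p < 0.05 and ≥ 90%
  of covariates are balanced.

PD cases themselves are classified from prescriptions (≥ 4 MAO-B
inhibitor fills, or ≥ 4 levodopa fills with a G20 reimbursement code),
validated against diagnosis codes. Seven sensitivity variants
(covariate-adjusted outcome model, ATC level-2 comparators, age and
comorbidity restrictions, a one-year lag, a general-population cohort)
re-run the pipeline with one modification each.

See `docs/methods.md` for the model details, design choices and
limitations.

## Worked example

Generate a synthetic registry with two genuinely protective drugs
planted among twelve (monthly log-odds effect −0.5 for ranitidine
A02BA02 and losartan C09CA01, all others null, with comorbidity-driven
confounded initiation), then run the screen:

```python
from ttescreen.simulate import generate_registry
from ttescreen.experiments import screen_demo_config, _SCREEN_DRUGS_12
from ttescreen.cohort import classify_pd_cases
from ttescreen.screen import run_screen

config = screen_demo_config(n_persons=15_000, theta=-0.5, seed=1)
snapshot, truth = generate_registry(config)
cases = classify_pd_cases(snapshot)          # 4977 PD cases
result = run_screen(snapshot, cases,
                    spec_defaults={"min_target_persons": 50},
                    seed=1, B=200, horizon_months=48,
                    targets=_SCREEN_DRUGS_12)
```

which prints (columns abridged):

```
target_atc  n_target  n_control  risk_target  risk_control     rd    rr  p_rd  p_by  balanced_fraction   hit
   A02BA02       878       1422       17.480        26.557  9.077 0.658 0.000 0.000                1.0  True
   C09CA01       934       1176       19.824        28.510  8.686 0.695 0.000 0.000                1.0  True
   C10AA05      1176        934       28.510        19.824 -8.686 1.438 0.000 0.000                1.0 False
   A02AA04       767       1533       27.006        20.800 -6.206 1.298 0.000 0.003                1.0 False
   A09AA02       655       1645       25.935        21.621 -4.313 1.199 0.020 0.146                1.0 False
   M01AE02      1071        874       22.794        20.960 -1.834 1.087 0.301 1.000                1.0 False
   ...
```

Reading the output: risks are 48-month mortality per 100 persons in
this scaled-down demonstration. The two planted drugs are the only
hits, with estimated risk ratios 0.66 and 0.70 and risk differences of
about 9 deaths prevented per 100 initiators. Their comparator drugs
(C10AA05, A02AA04, A09AA02) show *negative* risk differences for the
mirror-image reason — their control arms contain the protected
initiators — and the rd > 0 requirement correctly keeps them off the
hit list; the ten null drugs cluster around rr ≈ 1.

The same pipeline is scriptable from the shell:

```
ttescreen simulate --out reg --n-persons 20000 --seed 7
ttescreen classify --registry reg --out cases.csv
ttescreen trial    --registry reg --cases cases.csv --target A02BA02 --out trial1
ttescreen estimate --registry reg --cases cases.csv --target A02BA02 --out est.json
ttescreen screen   --registry reg --cases cases.csv --seed 7 --out results/
```

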