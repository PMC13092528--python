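# msprogrisk

Risk stratification and dynamic prediction of 5-year disability progression
in relapsing–remitting multiple sclerosis (RRMS), built for longitudinal
clinical-registry data.

People with RRMS accumulate disability at very different rates, and the
decision to start, escalate or stop disease-modifying therapy (DMT) hinges on
an individual estimate of progression risk. This package implements two
complementary tools for that estimate, plus everything needed to validate
them end to end on registry-shaped data:

* **A transparent 0–12 point score.** Four clinical features — **D**isease
  duration, **A**ge, **A**ge at onset, **E**DSS — each contribute integer
  points; the total stratifies patients into *very-low / low / medium / high*
  risk groups, and embedded reference tables return the 5-year progression
  risk (with 95% CI) conditional on DMT context (majority use over the
  window, or therapy at baseline). Treatment-group contrasts are corrected
  for indication bias by propensity-score matching (logistic model on age,
  sex, disease duration, EDSS; greedy nearest-neighbour 1:1 without
  replacement on the logit scale).
* **A dynamic landmark model.** Every eligible clinical visit is a landmark:
  covariates frozen at the visit (age, disease duration, EDSS, age at onset,
  time since baseline, and a ten-category summary of DMT exposure history)
  predict progression within the following five years through a
  class-weighted L1-penalized logistic regression,

  $\Pr(Y_{i}=1 \mid x_{i}) = \mathrm{logit}^{-1}(\beta_0 + x_i^\top \beta),
  \qquad \hat\beta = \arg\min_\beta \; \ell_w(\beta) + \lambda \lVert\beta\rVert_1,$

  with λ chosen by patient-grouped cross-validation. Landmarks whose
  remaining follow-up cannot determine the outcome are censored, which
  removes immortal-time bias by construction.

Progression is defined two ways and both are supported throughout:

* **clinical** — the neurologist-assigned transition to secondary
  progressive MS (SPMS) within five years of baseline;
* **objective** — relapse-independent confirmed worsening: EDSS ≥ 4.0 with
  pyramidal functional-system score ≥ 2, an EDSS increase ≥ 1.0 (reference
  ≤ 5.5) or ≥ 0.5 (reference ≥ 6.0), confirmed after ≥ 3 months in EDSS and
  in the leading functional system, with no relapse since the preceding
  evaluation.

A synthetic-registry generator with known ground truth (latent progression
dates, true hazards, assigned treatment classes) makes the whole pipeline
testable without access to patient data.

## Worked example

```python
import msprogrisk as mp

# generate a registry, screen it, and score a patient
records, truth = mp.generate_registry(mp.SimConfig(n_patients=1000, seed=7))
report = mp.apply_inclusion_criteria(records, mode="base")
print(f"{len(report.included_ids)}/{len(records)} patients included")

score = mp.compute_daae_score(
    disease_duration=12.0, age=52.0, age_at_onset=40.0, edss=6.0,
)
group = mp.assign_risk_group(score, mp.CLINICAL_RISK_SCHEMA)
risk, ci = mp.lookup_risk(group, "clinical", "majority_high")
print(f"score={score}  group={group}  5-y risk on high-efficacy DMT: "
      f"{risk}% (95% CI {ci[0]}-{ci[1]})")

rr = mp.risk_ratio(*[mp.lookup_risk("low", "clinical", c)[0]
                     for c in ("majority_high", "majority_low")])
print(f"high- vs low-efficacy risk ratio, low-risk group: {rr:.2f}")
```

prints

```
946/1000 patients included
score=11  group=high  5-y risk on high-efficacy DMT: 15.2% (95% CI 10.1-21.5)
high- vs low-efficacy risk ratio, low-risk group: 0.64
```

The landmark model follows the familiar model/results pattern:

```python
included = [r for r in records if r.patient_id in report.included_ids]
rows = mp.build_landmark_dataset(included, outcome_source="clinical")
train, test = mp.split_by_patient(rows, seed=7)
results = mp.ElieModel(train).fit(seed=7)
print(results.summary())          # coefficients, penalty, class weights
risks = results.predict(test)     # per-landmark 5-year probabilities
```

A `msprogrisk` command-line pipeline wraps the same functions
(`simulate`, `include`, `outcomes`, `exposure`, `score`, `match`,
`landmark`, `fit`, `predict`, `validate`); see `msprogrisk --help`.

## Documentation

`docs/methods.md` describes the statistical methods, the synthetic-data
model and its limitations, and the numerical choices in detail.
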