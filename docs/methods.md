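# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic-data model used for validation, and
the numerical choices made where the design was genuinely open.

## Cohort definition

Records enter the analysis cohort through explicit criteria, evaluated per
patient and reported per criterion code: RRMS course at baseline (A), no
other neurological disorder (B, an upstream flag), age ≥ 18 at baseline (C),
two or more clinical evaluations (D), follow-up strictly greater than 3
years with a 5 (±2)-year target window (E), EDSS recorded at the baseline
visit (F), and no prior use of the data (G, upstream flag). The
objective-outcome sub-cohort additionally requires relapse reporting (H,
guaranteed by the file schema here), complete functional-system (FS) data at
the visits the progression detector consumes (I), consecutive evaluations
more than 90 days apart (J), and no objective progression event on or before
baseline (K).

Time arithmetic is fixed throughout: ages and durations are day differences
divided by 365.25; "3 months" is 90 days; "5 years" is 1826 days. Follow-up
is last-visit date minus baseline date. The ±2-year clause of criterion E is
read as a cap on the observation window (min(follow-up, 7 years)) for
exposure computations rather than an exclusion — a patient followed 9 years
still enters, but the exposure window stops at year 7.

Criterion I deliberately takes the least destructive reading: missing FS
values exclude a patient only when they actually leave the progression
detector unable to decide (an abstention with no event found), not whenever
any FS value is absent anywhere.

## Objective progression detection

A visit qualifies as a progression candidate when (i) its EDSS is ≥ 4.0 and
its pyramidal FS score is ≥ 2; (ii) the EDSS increase over the reference is
≥ 1.0 when the reference EDSS is ≤ 5.5, or ≥ 0.5 when it is ≥ 6.0 (the
half-point grid makes the gap between those bands unreachable, which is
asserted at import); (iii) a later visit at least 90 days on confirms the
worsening — EDSS and the leading FS at or above their candidate values at
*every* visit from the candidate to the confirming visit; and (iv) no
relapse occurred in the interval (previous visit, candidate]. The earliest
qualifying candidate is the event.

Two quantities the definition leaves open are made explicit and
configurable:

* **Reference EDSS.** Default is the roving nadir — the minimum EDSS from
  baseline up to (excluding) the candidate — the strictest commonly used
  comparator; the fixed baseline-visit EDSS is available as an alternative
  (`ProgressionCriteria(reference="baseline")`).
* **Leading functional system.** The subsystem with the largest increase
  from the reference visit to the candidate, ties broken in the fixed order
  pyramidal → cerebellar → brainstem → sensory → bowel/bladder → visual →
  cerebral.

Missing FS data at a visit the detector needs produces a recorded
*abstention* at that candidate, never a silent pass. Two monotonicity
properties follow from the definition and are enforced by tests: adding a
relapse can only remove or postpone an event, and lengthening the
confirmation window can only remove events.

The clinical outcome is simpler: label 1 iff a clinician-assigned SPMS
transition date falls within (baseline, baseline + 5 years].

## DMT efficacy and exposure

Fifteen DMTs map to three efficacy tiers (high: rituximab, ocrelizumab,
mitoxantrone, alemtuzumab, natalizumab, ofatumumab; intermediate:
fingolimod, siponimod, daclizumab, laquinimod, cladribine; low:
interferon-beta, glatiramer acetate, teriflunomide, dimethyl fumarate).
Unknown drugs raise, never silently default.

Treatment episodes are half-open `[start, stop)` intervals; overlaps are
normalized by truncating the earlier episode at the later one's start. Two
exposure summaries with deliberately different denominators coexist:

* **Score-table scheme** — majority class = the efficacy class covering
  strictly > 50% of the whole observation window (untreated counts as its
  own state); switch flag = any *other* efficacy class covering strictly
  > 25% of the whole window.
* **Landmark scheme** — a switcher flag defined on treated time (≥ 50% of
  the window treated and ≥ 25% of treated time on a non-dominant class),
  plus a ten-level mutually exclusive history category: never treated;
  stable low/intermediate/high (≥ 50% of the window on one class with no
  class-to-class transition); switcher escalation / de-escalation /
  bidirectional (directional class-to-class transitions); switcher
  initiation (untreated → treated without discontinuation); switcher
  discontinuation (treated → untreated without re-initiation); switcher
  complex (fallback).

Because a history can match several descriptions, categories are assigned in
a fixed precedence: stability before switch patterns, bidirectional before
unidirectional, class-to-class patterns before initiation/discontinuation,
complex last. "No detected switching" in the stable categories means no
transition between distinct efficacy classes; stop/restart of the same class
does not break stability. Gaps shorter than a configurable
`gap_tolerance_days` (default 0) between same-class episodes are bridged;
longer untreated gaps insert explicit "none" states into the transition
sequence.

## The point score and its reference tables

The score is a sum of per-feature integer points over ordered bins of
disease duration, age, age at onset and EDSS, clamped to 0–12. Risk groups:
0–2 / 3–7 / 8–9 / ≥ 10 (clinical outcome) and 0–1 / 2–3 / 4–6 / 7–12
(objective outcome — the cutoffs are adapted because the objective
definition fires roughly twice as often as clinical judgment). Risk
percentages with 95% CIs are served from embedded reference tables keyed by
(outcome, DMT context, risk group); class-switch contexts are explicitly
unsupported (insufficient data) and raise. One table column (objective
outcome, baseline high-efficacy) is non-monotone across its first two
groups and is stored verbatim and flagged rather than smoothed.

The published point assignments are not publicly printed, so the package
ships (a) a clearly-labelled **demo** weight table with clinically sensible
gradients (duration up to 3 points, age up to 3, onset age up to 2, EDSS up
to 4) and (b) `derive_score_weights`, a simplified re-derivation: per
feature, a cubic B-spline logistic fit gives a smooth effect; the effect is
cut at quantile knots and monotonized (cumulative max/min in the direction
of the overall trend); an L1-penalized logistic regression over the
resulting ordinal features selects and weights them; retained coefficients
are rescaled to non-negative integers whose achievable maximum is 12. A
penalty that zeroes everything yields a table flagged degenerate rather
than an error. Every output names the table that produced it.

Risk ratios between table cells use the log-RR normal approximation for CIs
(`exp(log RR ± 1.96·SE)`, `SE² = 1/x₁ − 1/n₁ + 1/x₂ − 1/n₂`) and a pooled
two-proportion z-test for p-values. Ten of the thirteen published
between-context ratios reproduce exactly at printed precision from the
table cells; the other three differ by one unit in the last printed digit
because they were evidently computed upstream from unrounded proportions —
the tests check those for consistency with the interval the rounded cells
induce.

## Propensity matching

Treatment propensity is a logistic regression on age, sex, disease duration
and baseline EDSS (maximum likelihood; on perfect separation or
non-convergence a ridge-penalized fit is used and a warning raised).
Matching is greedy 1:1 nearest-neighbour without replacement on the
*logit* of the propensity score, no caliper, treated patients processed in
a seed-randomized order, ties broken by lowest control id (determinism
under a declared seed). Balance is reported as absolute standardized mean
differences before and after matching. Matching is performed cohort-wide,
then stratified by risk group, mirroring the order of the validation
protocol.

## Landmark model

Every visit with a recorded EDSS at or after baseline is a landmark. A row
is labelled 1 iff the outcome falls in (landmark, landmark + 1826 d];
visits on or after the outcome date contribute no row; event-free rows with
less than the full horizon of remaining follow-up are dropped (censored) —
together these guarantee no predictor or label uses information the
landmark could not have seen, the construction that removes immortal-time
bias. A permutation audit (rewriting post-horizon data and asserting
bit-identical rows) enforces this in the test suite.

The model is a class-weighted L1 logistic regression with a preprocessing
recipe learned on training data only: training-median imputation for
continuous predictors, one-hot encoding of the ten-level history category
(reference level: never treated), and standardization by training moments.
Class weights are n/(2·n_class). The penalty λ is chosen at minimum
cross-validated class-weighted log-loss over a log-spaced grid of 100
values spanning 1e-4–1e2, with 5 cross-validation folds grouped by patient
(folds never split a patient); the train/test split (80:20) is likewise at
the patient level. Decile stratification uses training-prediction quantile
boundaries; test rows are binned by those same boundaries and clamp into
the outer deciles. Fitted models serialize to a JSON model card (recipe
constants, coefficients, penalty, seed) and reload exactly.

## Validation metrics

Observed proportions get Wilson 95% intervals (better small-count coverage
than the normal approximation; oracle-checked against Clopper–Pearson).
Predicted-vs-observed comparisons use one-sample z-tests per stratum with
Bonferroni correction across strata; between-group comparisons use pooled
two-proportion z-tests (z² equals the 2×2 chi-square without continuity
correction). Calibration is summarized by the Brier score. Discrimination
is AUROC (rank-based) and accuracy at a 0.5 threshold, with
class-stratified percentile-bootstrap 95% CIs (2,000 resamples by default,
seeded). Class imbalance before discriminative testing is addressed by
synthetic minority oversampling (each synthetic point a convex combination
of a minority point and one of its k = 10 minority nearest neighbours)
followed by removal of both members of every Tomek link (cross-class mutual
nearest neighbours); the implementation is local, built on scikit-learn
nearest-neighbour queries. Missing covariates are multiply imputed by
chained equations (statsmodels MICE, predictive mean matching for all
columns — PMM keeps binary columns in-support, so no separate logistic
imputer is used) with m = 5 copies and 10 sweeps, pooled by Rubin's rules.

## Synthetic registry

The generator emulates the structure of a large observational MS cohort —
the schema and qualitative behaviour, not any empirical joint
distribution. Defaults: baseline age ~ Normal(37.1, 10.8) truncated to
18–70; disease duration ~ Gamma matched to mean 5.8 y, SD 7.3 y; baseline
EDSS a discretized Gamma with median 2 (IQR ≈ 1–3); visits every 182 ± 30
days (spacing never ≤ 90 days) over a follow-up drawn uniformly from 3–7
years; relapses Poisson at 0.35/year with exponential age decay.

Progression is a discrete-time hazard per inter-visit interval,
`p = 1 − exp(−exp(η)·Δt)`, with η linear in age (0.025/y), disease duration
(0.02/y) and current EDSS (0.30/point) around cohort-typical centres, plus
the log of the efficacy multiplier of the DMT class in force (none 1.0, low
0.80, intermediate 0.65, high 0.45 — a high-vs-low hazard ratio of ≈ 0.56,
in the range reported for real cohorts). The intercept is set so that about
10% of an included cohort carries a clinician progression label within 5
years. After the latent progression date the EDSS walk acquires a
non-remitting upward drift (steps 0/+0.5/+1.0 with probabilities
0.3/0.5/0.2) and pyramidal involvement (≥ 2 once EDSS ≥ 4); before it, the
walk is a symmetric ±0.5 wander. The clinician SPMS label is the latent
date plus an Exponential(mean 6 months) recognition delay, recorded with
probability 0.65 — delayed, imperfect recognition is what makes objective
events more frequent than clinical labels, matching the ordering seen in
registries.

DMT assignment carries indication bias: the probability of high-efficacy
therapy rises with baseline EDSS and (more weakly) with male sex, younger
age and shorter duration, scaled by a single `indication_bias` knob
(0 removes all confounding, which the tests exploit). Treatment state then
evolves by per-year escalation/de-escalation/initiation/discontinuation
rates, with escalation three times likelier after latent progression.
Missingness can be injected MCAR per FS field (default off).

What passing tests on this generator do **not** show: robustness to
informative visit schedules, measurement error in EDSS, relapse-associated
worsening (relapses here are independent of the EDSS walk), informative
dropout, or real-world drug-level heterogeneity within an efficacy class.
They do show that every pipeline stage is arithmetically correct, leakage-
free, and recovers planted signal in the direction and rough magnitude
configured.

## Problem sizes and numerical choices

The end-to-end validation (tests and the acceptance script) runs on a
3,000-patient synthetic registry — large enough for stable decile
incidences and matched-cohort balance diagnostics on one CPU. The
generator's determinism is byte-level for a fixed config. Fractions of
exposure windows are exact integer day counts over window days (oracle:
day-by-day enumeration, agreement to 1e-12). Decile boundaries with fewer
than 10 distinct predictions trigger a merged-bin warning rather than an
error. Bootstrap and matching orders are seeded; MICE reseeds the global
NumPy state per imputation copy for reproducibility.

## Known limitations

* The demo weight table is illustrative, not the published point table; the
  derivation routine is a simplified, documented stand-in for the original
  multi-stage procedure.
* The stable-category reading ("no class-to-class transition") and the
  category precedence order are one defensible resolution of a taxonomy
  that does not specify precedence; both are configurable and logged.
* Matching is plain greedy nearest-neighbour; optimal matching and
  weighting estimators are out of scope.
* Only the printed confirmation variant (3 months) of the objective
  definition is implemented, with `confirmation_days` configurable; PIRA
  re-baselining variants are not.
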