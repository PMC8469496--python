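# Methods

## The screening problem

VCS-type full blood count analysers report, per leukocyte population
(neutrophils NE, lymphocytes LY, monocytes MO, eosinophils EO), the mean
(`MN-`) and standard deviation (`SD-`) of each measurement channel: volume
(V, impedance), conductivity (C, radio frequency), and five optical
channels — MALS, UMALS, LMALS, LALS and axial light loss (AL2). Neoplastic
samples distort the size and internal complexity of leukocyte populations,
so these 56 cell population data (CPD) parameters carry screening
information long before a smear is reviewed.

`cpdscreen` has two halves: the *published discriminants* (fixed rules with
validated cutoffs, applied as a cascade) and the *calibration pipeline*
that derives equivalent rules from any labelled cohort.

## The decision cascade

Stage 1 computes the composite score
`(SD-V-NE × MN-UMALS-LY × SD-AL2-MO) / MN-C-NE` and flags a sample
neoplastic when the score exceeds its cutoff (shipped: 106.44). The form is
a product of positively oriented parameters over the negatively oriented
one, so the score is homogeneous of degree 1 in each numerator input and
degree −1 in the denominator. Stage 2 applies the single-parameter reactive
discriminant `MN-AL2-NE` (shipped cutoff 147.5) to remove infection-driven
false flags. Remaining samples receive advisory subtype flags (AML, APL,
ALL, CLL), evaluated independently per rule — they are not a partition, and
a missing input yields "not evaluated", never a silent negative.

Numerical conventions:

- **Strict comparisons.** All cutoffs are strict inequalities; a score
  exactly at a cutoff takes the negative label. This matches the published
  cutoff notation and makes ties deterministic.
- **No imputation.** The composite requires all four inputs; a missing
  parameter is an error naming the parameter, and a zero `MN-C-NE` is a
  domain error, never an infinite score.
- **Orientations.** The four screening parameters were published with
  orientations (high SD-V-NE, MN-UMALS-LY, SD-AL2-MO and low MN-C-NE mark
  neoplasia). The reactive discriminant and the subtype rules were
  published as cutoffs only; the shipped defaults (low MN-AL2-NE marks
  neoplastic, all subtype rules high-positive) are explicitly provisional
  configuration, chosen on haematological plausibility, and the classifier
  refuses to apply a rule whose orientation is unset rather than guess.
  The calibration pipeline re-learns orientations from data.
- **Audit.** Every rule evaluation appends (rule, inputs, score,
  comparison, outcome) to an ordered audit trail; stage-2/3 rules are never
  evaluated for stage-1-negative samples.

## Calibration pipeline

Given a labelled cohort and a binary contrast:

1. **Candidate gate.** Per parameter, a two-tailed two-sample t-test
   between the contrast classes; candidates require p < 0.05. The Welch
   (unequal-variance) form is the default, the pooled Student form is a
   flag. Lilliefors-corrected Kolmogorov–Smirnov normality is recorded per
   group but does not gate the pipeline. No multiplicity correction is
   applied by default (matching the original derivation across 126
   parameters); Benjamini–Hochberg is available by flag and is a documented
   deviation when used.
2. **Multi-group screens** (≥ 3 groups, e.g. subtype contrasts) branch on
   Levene's test with mean centring at p < 0.05: homogeneous variances →
   one-way ANOVA with Tukey HSD post hocs; heterogeneous → Welch ANOVA with
   Games–Howell post hocs. The omnibus p gates selection; pairwise p-values
   are reported alongside.
3. **ROC.** The empirical AUC equals the Mann–Whitney probability that a
   random positive scores beyond a random negative with ties weighted ½
   (the test suite checks exact equality against a brute-force pair-count).
   Orientation is chosen so AUC ≥ 0.5 and recorded. The 95% CI is DeLong's
   (midrank form); Hanley–McNeil is available by flag. The CI method used
   in the original derivation is unstated, so this is a package choice, not
   a reproduction.
4. **Cutoff selection.** Candidate thresholds are midpoints between
   adjacent distinct observed values. The default policy maximises Youden's
   J = sensitivity + specificity − 1, breaking ties first by minimal
   |sensitivity − specificity|, then by the lower threshold; cutoffs are
   reported to 2 decimals. A "constrained" policy maximises J subject to
   sensitivity ≥ 0.80 and specificity ≥ 0.80 and errors when infeasible.
5. **Composite building.** Parameters passing AUC > `auc_min` (default 0.9)
   combine as numerator (high-positive) over denominator (low-positive);
   the composite cutoff is re-derived by the same ROC/cutoff machinery on
   the composite scores.

`DiscriminantCalibrator` wraps steps 1, 3, 4, 5 as a scikit-learn estimator
(`fit`/`predict`/`decision_function`, fitted attributes `screen_results_`,
`rule_`, `roc_`); `CascadeClassifier` wraps the cascade the same way. Both
compose with sklearn model selection on DataFrames whose columns are
canonical parameter names.

## Diagnostic accuracy statistics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN) as exact integer ratios; a zero denominator reports the
statistic as undefined rather than 0 or 1. The default 95% CI is the
continuity-corrected Wilson score interval in Newcombe's closed form, the
method used by the common clinical test-evaluation calculators — it
reproduces the published validation intervals, e.g. (0.56, 0.93) for an
NPV of 16/20 and a lower bound of 0.97 for a PPV of 141/141. Plain Wilson
and Clopper–Pearson are available by flag. Percentages are rendered at two
decimals and CI bounds as two-decimal proportions.

## Synthetic cohorts

No patient-level CPD cohort is deposited for this problem, so testing uses
a seeded generator. Each diagnosis group draws every parameter from a
configurable marginal: `SD-` parameters default to lognormal (strictly
positive, right-skewed, as dispersion statistics are), parameterised by
their natural-scale mean and SD; `MN-` parameters default to normals
truncated at zero. Within-group correlation defaults to independence, with
an optional single-factor correlation per cell type (rho per population) to
stress-test composite scores.

The reference configuration (`paper_like_config`) uses the real cohort
sizes — 1056 normal, 47 reactive, 62 AML, 30 APL, 54 ALL, 47 lymphoma, 28
CLL, 12 CML, 12 MDS; 1348 samples — with effect sizes chosen once so that:

- exactly the four screening parameters separate neoplastic from
  non-neoplastic samples with AUC > 0.9, at effect sizes placing the
  published cutoffs near the class crossing points (e.g. non-neoplastic
  SD-V-NE ≈ 15 ± 2.2 vs neoplastic ≈ 26 ± 5);
- `MN-AL2-NE` is elevated in reactive samples (≈ 156 ± 6) relative to both
  normal (≈ 143 ± 6) and neoplastic (≈ 141 ± 7) samples, giving a
  neoplastic-vs-reactive AUC near 0.95 with the low-positive orientation;
- subtype parameters show moderate one-vs-rest shifts (AUC ≈ 0.7–0.8),
  consistent in direction with the shipped subtype-rule orientations;
- the remaining ~40 parameters are exchangeable noise across groups.

What passing tests on these cohorts shows: the pipeline recovers configured
separations at realistic sample sizes, its type-I behaviour is calibrated
(≈ 5% of null parameters pass the p < 0.05 gate, essentially none reach
AUC > 0.9), and re-derived cutoffs are stable (composite cutoff within
±10% of its across-seed mean at these sample sizes). What it does not show:
performance on real instrument data, where parameters are correlated within
cell type, marginals are not exactly (log)normal, and pre-analytical
artefacts exist. The retrospective AUCs and cutoffs of the published tables
(0.989, 18.95, 147.5, …) depend on the unavailable patient cohort; they are
shipped as constants and exercised by the property suite, not re-derived.

## Problem sizes and determinism

Library code is deterministic; all randomness lives in explicitly seeded
test fixtures and the generator's mandatory seed. The test suite uses the
full 1348-sample reference cohort where group structure matters, 100 seeded
replicates for null-calibration rates, 10 seeds for recovery/stability
checks, and 200 random instances for ROC oracle equivalence. The acceptance
script runs two reference-size cohorts (train and held-out) per invocation.

## Known limitations

- Subtype-rule orientations and the reactive-discriminant orientation are
  provisional defaults, not published facts; deployments should calibrate
  them on local data.
- Subtype flags cover AML, APL, ALL and CLL only; no discriminant exists
  for lymphoma, CML or MDS, and the screen is a flagging aid, not a
  replacement for morphology, immunophenotyping or genetics.
- The generator models marginal separations, not the full joint
  distribution of instrument CPD output; within-group variances and
  correlations are plausible choices, not estimates.
- One published sensitivity CI (0.89, 0.96 for 262/266) is internally
  inconsistent with its own point estimate (98.50%) and is not reproducible
  by any standard interval; it is treated as a typesetting error.
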