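# Methods

This note documents the statistical machinery in `mimicscale`: what each
component computes, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Setting and data model

The package models a retrospective thrombolysis cohort: consecutive
adult (≥ 21 y) patients treated with intravenous thrombolysis for
suspected acute ischemic stroke, each with pre-treatment clinical
variables (age, sex, SBP/DBP, NIHSS, and nine binary history/examination
flags) and an adjudicated final diagnosis — ischemic stroke, TIA, or
stroke mimic. For every mimic-vs-stroke analysis, TIA is pooled with
ischemic stroke as "true stroke" (the comparison of clinical interest is
vascular vs non-vascular). One flag backs both "facial droop" (FABS) and
"facial weakness" (TMS), and one backs "seizure disorder"/"seizures"/
"epilepsy" across the three scales that use them: all scales are rated
from the same chart review and the source data record no finer
distinction. Records with any missing field are excluded at read time
and counted, never silently dropped.

## The four scales

Scored literally from their published item tables, with every threshold
comparison strict as printed: age < 50, SBP < 150 mmHg, NIHSS > 14. The
Khan age bands are read as < 50 / 50–70 inclusive / > 70, the only
reading that partitions the integers. Khan's vascular component counts
distinct factors among hypertension, hyperlipidemia and diabetes; atrial
fibrillation forces the component to 0 regardless of the others. Ages
are integer completed years, which makes TMS a multiple of 0.2 (reported
to one decimal). TMS's theoretical minimum of −6 is unattainable for an
adult cohort; the effective minimum is 0.2·21 − 6 = −1.8.

Orientation is part of each scale's definition: higher FABS/sFABS/Khan
and *lower* TMS indicate mimic. ROC machinery negates lower-is-mimic
scores internally so the positive (mimic) class always lies on the high
side.

## Group comparison statistics

**Odds ratios.** The default estimator is the cross-product ratio with
the Haldane–Anscombe correction — 0.5 added to *all four* cells
unconditionally — with a Wald CI on the log scale using the
cell-reciprocal variance of the corrected cells. The unconditional (not
only-if-zero) correction is the one that reproduces the reference
characteristics table: seven of its nine categorical odds ratios match
at printed precision, including rows with no zero cell whose uncorrected
ratios differ materially (migraine: corrected 23.0 vs uncorrected 25.5).
The two smallest-count rows (seizure, psychiatric history) land exactly
one unit in the last printed digit away (computed 2.73 / 7.51 vs printed
2.72 / 7.52); the publication's estimator for those rows is unstated and
is not the corrected cross-product ratio. The uncorrected and
only-if-zero variants remain available; with no correction, a zero in a
denominator cell raises rather than fabricating a value.

**Chi-square and Fisher.** Pearson's chi-square on 1 df (closed form,
optional Yates continuity correction, default off — the uncorrected form
reproduces the reference table's seizure and hypertension p-values of
0.706 and 0.038). Fisher's exact two-sided p (hypergeometric tail sum,
via scipy) is exposed alongside for small expected counts; the reference
table's p-values are heterogeneous (its psychiatric-history p of 0.022
matches neither Pearson nor Yates), so both tests are reported and no
per-row selection is guessed. The asymptotic and exact tests agree
closely only in the decision-relevant tail; near p = 1 the two-sided
Fisher sum saturates by discreteness and numerical agreement bounds do
not apply.

**Rank test and proportions.** Mann–Whitney U with midrank ties and the
tie-corrected normal approximation (scipy) for continuous variables.
Binomial proportions (sensitivity, specificity, PPV, NPV) carry
Clopper–Pearson exact 95% intervals — the choice that reproduces the
printed TMS sensitivity interval (86.9–94.5) at one decimal.

## ROC analysis

The empirical AUROC is computed by midranks and equals the Mann–Whitney
cross-pair estimator exactly, ties counted half — an identity the test
suite asserts on arbitrary inputs. Variance and covariance of paired
AUROCs follow DeLong's placement-value (structural-component)
decomposition: `cov = S₁₀/n₊ + S₀₁/n₋` with sample covariances of the
per-observation placements; the paired test statistic is
`z = (A₁ − A₂)/√(v₁ + v₂ − 2c)`. If the variance of the difference is
zero (one score a monotone transform of the other), p = 1 by convention
when the AUCs are equal. AUC CIs are Wald on the AUC scale with the
DeLong SE, truncated to [0, 1], matching the symmetric printed intervals
(0.750 ± 0.121).

Youden cutoffs maximize J = Se + Sp − 1 by exhaustive scan over
midpoints between consecutive distinct scores plus ±∞; ties break toward
higher sensitivity, then the lower cutoff, making the result
deterministic. Cutoffs are reported on the scale's original axis.

**Positive-test convention.** The reference performance table is
integer-consistent only when sensitivity is measured over the 240 true
strokes and specificity over the 17 mimics (91.3% = 219/240,
58.8% = 10/17, …), i.e. the "positive test" is the stroke-indicating
side of the cutoff. That stroke-positive convention is the default;
the mimic-positive convention is available and tagged in every row.
Likelihood-ratio CIs use the standard log method. Rows reconstructed
from published summary sensitivity/specificity round to integer 2×2
counts before any arithmetic, so derived PPV/NPV/LRs are internally
consistent by construction.

## Decision tree

A deliberately small binary CART-style learner over a configurable
feature set (default: age, migraine, hypertension, psychiatric history —
the univariately significant variables in this setting):

- **Splitting.** Exhaustive scan of (feature, threshold) candidates —
  midpoints between consecutive distinct values for ordered features,
  presence for booleans — minimizing child-size-weighted Shannon
  entropy; a split must strictly reduce entropy and respect the minimum
  node size. Equal-gain ties resolve by lexicographic feature name then
  smaller threshold, so the tree is invariant to record order.
- **Pruning.** Reduced-error pruning: bottom-up replacement of a subtree
  by its majority leaf whenever holdout error does not increase, which
  guarantees the pruned tree's holdout error never exceeds the full
  tree's. The holdout is a stratified 30% of the training data by
  default (the published analysis names the pruning method but not its
  holdout construction).
- **Defaults.** min node size 5, max depth 4, seed required. These are
  package choices: depth 4 comfortably represents the published
  three-level tree, and size-5 leaves keep probabilities meaningful with
  only ~17 mimics per cohort.
- **Prediction and risk.** A leaf predicts its training mimic fraction;
  the class call thresholds at 0.5 with ties to stroke (the safer
  clinical default). Risk classes follow the proposed bands: high above
  60%, low below 5%, both strict, else uncertain.
- **Cross-validation.** Stratified k-fold (default 10, capped at the
  minority-class size), grow-then-prune within each training fold,
  pooled out-of-fold confusion matrix. Reported sensitivity/specificity
  use the same stroke-positive convention as the performance table.
- **Fixed structure.** `published_tree` evaluates the proposed clinical
  tree (migraine at the root; age ≤/> 45 among the migraine-free;
  psychiatric history among the older migraine-free) on any cohort,
  filling leaf counts from the data. Structural recovery of that tree by
  the learner is probabilistic and is exercised on planted cohorts.

## Synthetic cohort generator

`generate` draws, per patient: the class label (Bernoulli at 17/257
mimic prevalence; the true-stroke remainder split stroke : TIA at
226 : 14), then class-conditional covariates — age from a Normal
truncated to [21, 100] and rounded to integer years (stroke 66 ± 13,
mimic 57 ± 17), SBP/DBP from truncated Normals (160 ± 28 / 91 ± 20 and
161 ± 34 / 90 ± 15), NIHSS from a shifted negative binomial (dispersion
2.0) clipped to the printed ranges (1–32, 2–30) with the mean calibrated
once so the n = 10⁴ sample median lands within ±1 of the printed medians
(9 and 6; calibrated means 9.4 and 5.0 above the shifts), and nine
independent Bernoulli flags at the class prevalences of the reference
characteristics table. Everything is driven by one `numpy`
`default_rng(seed)`, so equal parameters give byte-identical cohorts.

Two prevalences the reference tables never report — facial droop and
isolated sensory deficit — carry placeholder defaults (stroke 0.60/0.05,
mimic 0.30/0.20) flagged in the generator metadata. Any FABS/sFABS
performance computed on synthetic data depends on those placeholders and
must not be read as a reproduction of the published FABS rows.

What the generator does **not** emulate: within-class correlation
between risk factors (real vascular factors co-occur; flags here are
independent, and the test suite asserts that independence), any
age–NIHSS or BP–history dependence, missing-data mechanisms beyond an
optional uniform dropout, and the unrecorded clinical factors that drove
the original adjudication. Passing pipeline tests on synthetic cohorts
therefore demonstrates correctness of the *estimators and plumbing*, not
clinical performance on real patients; the published cohort-dependent
numbers (AUROCs 0.75/0.61/0.61/0.60, the 13.6 TMS cutoff, the 8.6% CV
misclassification) are not reproducible without the patient-level data
and are deliberately not targets anywhere in the package.

`generate_planted_tree_cohort` instead draws labels from an explicit
conditional table P(mimic | migraine, age band, psychiatric history)
with precedence migraine → young age → psychiatric history, mirroring
the proposed tree's structure; it exists for structure-recovery and
pruning experiments.

## Numerical conventions and edge cases

- Reported ORs round to 3 significant figures, percentages to one
  decimal, TMS to one decimal; JSON reports keep full precision and the
  markdown rendering applies the display rounding.
- Degenerate inputs fail loudly: single-class cohorts, empty groups,
  zero marginals, out-of-range probabilities and non-finite cutoffs
  raise with the offending quantity named. A constant scale yields
  AUROC 0.5 with a logged warning rather than an error.
- PPV/NPV with an empty predicted margin are reported as absent, not
  fabricated.
- The Youden scan, the entropy split scan and the pruning pass are
  exhaustive/deterministic; no stochastic optimizer is involved.
  Stochastic components (generator, fold assignment, grow/prune
  partition) are all seeded.
- Problem sizes used by the test suite and acceptance script are chosen
  for precision at desk scale: n = 10⁵ cohorts for moment-recovery
  checks (≈ 3 SE discrimination), 100-seed replicate batches for
  pruning/root-recovery rates, 2000-replicate bootstraps for the DeLong
  variance cross-check, and n = 257 for end-to-end pipeline runs.

## Known limitations

- The characteristics-table CI bounds printed in the reference (e.g.
  migraine 3.60–147) match no single standard interval we computed;
  Wald-on-corrected-cells is used and documented, and CIs are not
  reproduction targets.
- Two published odds ratios (seizure 2.72, psychiatric 7.52) differ from
  the corrected cross-product ratio by one print unit, as noted above.
- The tree learner offers no cost-complexity pruning, surrogate splits,
  missing-value handling, or forests — by design, matching the scale of
  the clinical problem.
- Scale performance on synthetic FABS/sFABS inputs inherits the
  placeholder droop/sensory prevalences.
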