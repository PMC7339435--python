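# mimicscale

A validation toolkit for **stroke-mimic clinical prediction scales**.

About 2–30% of patients treated for suspected acute ischemic stroke turn
out to be *stroke mimics* — presentations that look like stroke (functional
disorders, migraine, post-ictal weakness, …) but are not vascular.
Thrombolysing a mimic exposes the patient to hemorrhage risk with no
possible benefit, so emergency physicians want bedside rules that flag
likely mimics from clinical information alone. `mimicscale` implements the
full analysis pipeline used to externally validate four published
point-based mimic prediction scales and to derive a simple clinical
decision tree, together with a calibrated synthetic-cohort generator so
that every stage runs end-to-end without access to patient-level data.

It is aimed at biostatisticians and clinical-research engineers who need a
tested, reproducible implementation of:

- **Scales** — FABS, simplified FABS (sFABS), TeleStroke Mimic Score (TMS)
  and the Khan score, scored exactly from their published item tables.
  FABS/sFABS/Khan rise with mimic-likeness; TMS falls (higher TMS → more
  likely true stroke).
- **Group comparisons** — 2×2 cross-tabulations with Haldane–Anscombe
  continuity-corrected odds ratios `OR = ((a+½)(d+½))/((b+½)(c+½))` and
  Wald log-scale CIs, Pearson chi-square (optional Yates), Fisher's exact
  test, Mann–Whitney U, and Clopper–Pearson exact binomial intervals.
- **Discrimination** — empirical ROC curves; AUROC via the Mann–Whitney
  cross-pair estimator `P(S⁺ > S⁻) + ½P(S⁺ = S⁻)`; DeLong
  placement-value covariance and the paired DeLong z-test for comparing
  correlated AUROCs; Youden-index cutoffs (`J = Se + Sp − 1`, exhaustive
  scan over midpoints); full operating-point rows (Se, Sp, PPV, NPV,
  LR±) with exact and log-method CIs.
- **Decision tree** — a from-scratch CART-style learner with Shannon
  entropy splitting, reduced-error pruning against a stratified holdout,
  stratified k-fold cross-validation, and the three-way mimic risk
  classification (high > 60%, low < 5%, uncertain otherwise). A fixed
  published-structure mode (migraine → age > 45 → psychiatric history)
  evaluates the proposed clinical tree on any cohort.
- **Synthetic cohorts** — a seeded generator reproducing the validation
  cohort's class-conditional structure (n = 257, 17 mimics; class-specific
  age/BP normals, shifted negative-binomial NIHSS, independent Bernoulli
  history flags), plus planted-effect cohorts for tree-recovery
  experiments.

## Worked example

```python
from mimicscale import ContingencyTable, odds_ratio, performance_from_summary

# TMS row of the performance table, rebuilt from its published
# sensitivity/specificity and the 240/17 group sizes:
row = performance_from_summary(0.913, 0.588, 240, 17, scale="tms", cutoff=13.6)
print(row.counts)                       # (219, 21, 10, 7)  = TP, FN, TN, FP
print(round(100 * row.ppv.estimate, 1)) # 96.9
print(round(100 * row.npv.estimate, 1)) # 32.3
print(round(row.lr_neg.estimate, 2))    # 0.15

# Migraine vs mimic status (3/17 mimics vs 2/240 true strokes):
est = odds_ratio(ContingencyTable(a=3, b=14, c=2, d=238))
print(round(est.estimate, 1))           # 23.0
```

A TMS above 13.6 confirms true stroke strongly (PPV 96.9%) but a low TMS
rules it out poorly (NPV 32.3%) at 6.6% mimic prevalence, and a migraine
history multiplies the odds of being a mimic about 23-fold. The
`examples/` directory holds one short script per capability
(`score_patients.py`, `diagnostic_accuracy.py`, `roc_comparison.py`,
`decision_tree.py`, `synthetic_cohort.py`); each prints its numbers with a
sentence on what they mean.

## Command line

```bash
mimicscale simulate --n 257 --seed 1 -o cohort.csv   # cohort + YAML metadata
mimicscale score cohort.csv scored.csv               # append the 4 scale columns
mimicscale table2 cohort.csv                         # characteristics summary
mimicscale table3 cohort.csv --reference tms         # performance table
mimicscale tree cohort.csv --seed 1                  # fit + CV report
mimicscale validate cohort.csv --seed 1 -o report/   # full JSON + markdown report
```

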