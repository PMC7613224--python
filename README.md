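# metabodx

Plasma ¹H-NMR metabolomics diagnostics: can the blood metabolome flag
solid tumors in patients referred with nonspecific symptoms, where the
cancer prevalence is low (~8%) and no organ-specific test applies?

`metabodx` implements the complete modelling pipeline for that question
as a tested, reusable Python package:

* **Preprocessing** — chemical-shift referencing to the lactate doublet at
  δ = 1.33 ppm, integration of each spectrum into 0.01-ppm buckets over
  0.20–9.68 ppm with the residual-water band excluded (898 buckets at the
  defaults), and Pareto scaling, x′ = (x − x̄)/√s, fitted on training data
  only.
* **OPLS-DA via NIPALS** (written from scratch) — for y ∈ {−1, +1} and
  column-scaled X: w ∝ Xᵀy; per orthogonal component t = Xw,
  p = Xᵀt/tᵀt, w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o,
  X ← X − t_o p_oᵀ; finally b = yᵀt/tᵀt and discriminant score s = b·(Xw).
  The orthogonal-component count (0–9) maximises the 7-fold internal
  cross-validated Q² = 1 − PRESS/SS.
* **Discriminant metabolites** — variable importance in projection,
  VIP_j = √J·|w_j| (mean squared VIP ≡ 1); buckets with VIP > 2 count as
  significant.
* **Validation** — repeated stratified 10-fold external cross-validation
  (scaling and component selection refit inside every training fold)
  against a permutation null, compared per metric with two-sided
  Kolmogorov–Smirnov tests.
* **Diagnostics** — ROC curves with the closest-to-top-left operating
  threshold, confusion panels (sensitivity, specificity, NPV, PPV,
  balanced accuracy = (sens+spec)/2, F₁ = 2TP/(2TP+FP+FN)), Wilson score
  intervals, Fisher exact tests, and Z comparisons (DeLong for ROC pairs,
  pooled-variance for proportions).
* **Synthetic cohort generator** — Lorentzian forward model over a
  28-metabolite plasma resonance library with lognormal biological
  variability, per-metabolite chemical-shift jitter and additive noise,
  emulating the study structure (n = 284, rare positive class, lipoprotein
  resonances down / glucose, NAC1, threonine up in cancer), so the whole
  pipeline is testable without patient data.

## Worked example

The numbered scripts under `analysis/` replay the study on a seeded
synthetic cohort (284 patients, 23 solid tumors, split 192/92 by referral
order) and write their tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_preprocess.py
python 03_train_model.py
python 04_validate.py
python 05_evaluate_test_set.py
python 06_univariate_panel.py
```

Selected output (seed 1):

```
=== 03_train_model.py ===
modelling set n=192 (17 cancers); test set n=92 reserved
internal 7-fold Q2 by orthogonal components: 0.355 0.117 0.025 -0.145 ...
selected n_ortho=0; Q2=0.355, R2Y=0.412; 35 buckets with VIP>2
VIP>2 buckets map to: glucose, lipid_ch2, lipoprotein_ch3, nac1, saturated_lipid, threonine

=== 04_validate.py ===
balanced_accuracy  real 0.807 vs null 0.532 (KS D=0.670, p=3.38e-30)

=== 05_evaluate_test_set.py ===
modelling CV ROC AUC 0.973; top-left threshold 0.2906
test set (n=92, 6 cancers): AUC 0.922
  counts tp=4 fp=4 fn=2 tn=82
  sensitivity        66.7% (95% CI 30-90)
  specificity        95.3% (95% CI 89-98)
  npv                97.6% (95% CI 92-99)
  Fisher one-sided p = 0.0003; DeLong modelling-vs-test Z = 0.84 (p = 0.40)
```

Reading this: the model recovers all six injected discriminators in the
VIP > 2 set, its cross-validated balanced accuracy (0.81) clearly beats
the permutation null (0.53), and the threshold chosen on the modelling
set transfers to the untouched test third with AUC 0.92 and a
significantly-better-than-chance classification (Fisher p < 0.001). The
high NPV with modest sensitivity is the expected operating regime of a
rule-out test at 8% prevalence. The univariate panel (script 06) shows
each flagged metabolite moving in its injected direction, with
threonine's fold change diluted toward 1 because its CH₃ resonances
overlap lactate — a faithful rendition of a real quantification problem.

A thin CLI mirrors the same stages
(`metabodx simulate|preprocess|split|train|validate|evaluate|report`).

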