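# Methods

This note documents the models, numerical conventions and design choices
behind `metabodx`, and what the synthetic-data experiments can and cannot
show about real plasma spectra.

## The modelling problem

A cohort of unwell patients with nonspecific symptoms is screened for
solid tumors from 1D ¹H-NMR plasma spectra. The positive class is rare
(~8%), the feature space is large (898 spectral buckets) relative to the
sample (n = 284), and the clinical question is asymmetric: the classifier
is most useful as a high-NPV rule-out test. The pipeline therefore
couples a single-component discriminant model with heavy resampling-based
validation and threshold selection on an explicit ROC criterion.

## Preprocessing

* **Referencing.** Spectra are aligned by shifting the ppm axis so the
  maximum intensity inside a 1.20–1.45 ppm window lands exactly on the
  lactate doublet position, 1.33 ppm. Window-maximum referencing is the
  simplest faithful implementation of "referenced to lactate"; it
  presumes the lactate line dominates that window, which holds for CPMG
  plasma spectra (and for the synthetic library by construction). If the
  window maximum does not rise 5 robust-noise units (1.4826·MAD) above
  the spectral median, no shift is applied and a warning flag is set.
* **Bucketing.** Buckets are half-open intervals [left, left + 0.01)
  ascending over 0.20–9.68 ppm. Integrals are exact trapezoidal areas of
  the piecewise-linear trace between bucket edges (edges falling between
  grid points are handled by interpolating the running integral), so a
  constant unit intensity yields exactly width-sized buckets and
  bucketing is exactly additive over intensity splits. Buckets
  overlapping an excluded interval by more than 10⁻¹² ppm are dropped;
  the default water exclusion [4.50, 5.00) is standard plasma practice
  (the source protocol says only that the residual water region was
  excluded) and leaves 948 − 50 = 898 buckets. Axes may be stored in
  either direction; everything normalises to ascending internally.
* **Pareto scaling.** x′_j = (x_j − mean_j)/√sd_j with the n−1
  denominator, fitted on the modelling (or training-fold) samples only
  and applied frozen to held-out data — any other choice leaks the test
  set into the scaler. Zero-variance columns are flagged degenerate and
  map to 0. No total-area or quotient normalisation is applied by
  default; only Pareto scaling is part of the modelled protocol.

## OPLS-DA

Classes are coded y ∈ {−1, +1} (symmetric coding makes 0 the natural
prior cut). For a single response the orthogonal projection needs no
iterative loop; the fit is deterministic:

1. w = Xᵀy / ‖Xᵀy‖ on the scaled, undeflated X;
2. per orthogonal component (on the current X):
   t = Xw, p = Xᵀt/tᵀt, w_o ∝ p − (wᵀp)w (normalised),
   t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o, X ← X − t_o p_oᵀ;
3. on the deflated X: t = Xw, b = yᵀt/tᵀt.

All normalisations carry a 10⁻¹² floor; a predictive weight below the
floor (no covariance between X and y, e.g. constant X) is rejected as
signal-free. Exactly one predictive component is extracted — standard for
a binary response.

**Scores and Q².** The discriminant score of a sample is s = b·(Xw) after
deflation; a row at the training mean scores exactly 0, and since t is
centred, b is identical whether y is centred or not. Cross-validated
predictions are ŷ = ȳ_train + s, and Q² = 1 − PRESS/SS with SS around the
full-sample mean, so the mean predictor scores exactly 0. This matters
at 8% prevalence: regressing the uncentred y on a centred score without
the ȳ offset would bound Q² below −1 even for a perfect classifier.

**Component selection.** Candidates 0–9 orthogonal components are scored
by stratified 7-fold cross-validated Q² on one shared fold draw (folds
redrawn, up to 100 times, if a training fold would lose a class); the
argmax wins, ties break toward fewer components. Because the components
are nested for a fixed w, one pass to the maximum count yields every
candidate's held-out predictions, so selection costs one fit per fold,
not ten. The alternative reading of "optimal Q²" — stop at the first
non-improving component — is not implemented; strict argmax with the
fewest-components tie-break is simpler and equivalent in the common case.

**VIP.** With a single predictive component and orthogonal variation
y-unrelated by construction, VIP_j = √J·|w_j|, which satisfies
mean(VIP²) = 1 exactly; buckets with VIP > 2 are flagged. VIP is
computed on the predictive component only.

## Validation

External validation uses repeated stratified k-fold CV (default
k = 10 × 100 repeats = 1,000 trained models; the desk-scale runs in this
repository use 10–20 repeats and record their sizes in every output).
Inside each training fold the full pipeline is refit: Pareto scaling,
internal component selection, final fit. Held-out samples are classified
at the prior cut s ≥ 0 and per-fold sensitivity, specificity and accuracy
are recorded; folds whose held-out portion lacks a class (possible when
the rare class has fewer members than k; a warning marks the relaxed
stratification) carry NaN for the undefined metric. Repeat r draws its
randomness from (seed, r) alone, so any repeat is reproducible in
isolation.

The permutation null shuffles the labels once per permutation (default
100, minimum 20) and reruns the identical scheme. Real and null metric
vectors are compared per metric with the two-sided two-sample KS test
(exact method when both vectors have ≤ 10 entries). On no-effect cohorts
the real-versus-null comparison stays non-significant in ≥ 90% of seeds
and mean balanced accuracy sits at 0.50 ± 0.05; note that the fold-level
accuracy at the prior cut is not itself the headline metric — balanced
accuracy is threshold-robust under the null, plain accuracy is not.

A degenerate input (identical rows in X) makes every fold signal-free;
such folds fall back to all-zero scores and are counted in the scheme
echo, so real and null distributions coincide exactly instead of
aborting the whole resampling run.

## Thresholds and diagnostics

The operating threshold is the ROC point closest (Euclidean) to the
top-left corner, with ties broken toward higher specificity and then the
higher threshold. By default the ROC is built on the modelling set's
cross-validated scores (per-sample means of the out-of-fold scores
across repeats) rather than training-fit scores, which would be
optimistic; both modes exist behind `threshold_source`. The threshold is
then transferred unchanged to the independent test set, which is read
exactly once, after threshold selection (the run log in every report
bundle records the stage order).

ROC curves use "positive if score ≥ threshold" with thresholds at the
distinct observed scores plus a +∞ endpoint; the trapezoidal AUC equals
the Mann–Whitney statistic with half credit for ties. Wilson score
intervals cover all reported proportions (their k = 0 and k = n bounds
are exactly 0 and 1). The Fisher exact test reports the one-sided
(better-than-chance) and the point-probability two-sided p-values. ROC
pairs are compared with a Z built on the DeLong variance estimator —
stated here as this package's choice of estimator, since "Z-statistic
comparison of curves" admits several constructions; proportion pairs use
the pooled-variance two-proportion Z.

Report output rounds percentages half-up to the nearest integer.

## Synthetic cohorts: what they emulate, and what not

Each metabolite is a set of unit-area Lorentzian resonances; per-sample
concentrations are lognormal around class medians (biology is
multiplicative; the class effect multiplies the median by 2^log2FC and
leaves the dispersion alone); each metabolite gets one shared Gaussian
ppm jitter per sample (default sd 0.002 ppm, mimicking pH-dependent
drift), and the trace receives additive Gaussian noise. Labels are
assigned by exact count round(prevalence·n), shuffled by seed, so small
cohorts never lose a class. The default axis is 32,768 points over
0–10 ppm stored descending (display convention); tests and analysis
scripts use 4,096-point axes, which oversample the default buckets
four-fold and cut runtime.

Defaults mirror the target study: n = 284, prevalence 24/284, cancer
effects "lipoprotein resonances down; glucose, NAC1, threonine up" and a
metastatic effect set "threonine, β-hydroxybutyrate, NAC1, NAC2 up;
–CH₃ CM/VLDL and unsaturated lipid modestly down", both at
|log2FC| = 0.7 (0.3 for the modest lipid decreases); biological
lognormal sigma 0.35 (≈36% concentration CV, typical inter-individual
metabolite variability); noise sd 0.2 intensity units (a high-field
cryoprobe regime where all library metabolites are quantifiable).

The resonance library (28 metabolites, versioned JSON) deserves three
honest caveats:

* Positions are quoted at 0.005-ppm resolution, which places sharp
  singlets mid-bucket. Real peak positions are arbitrary relative to the
  bucket grid; the pathological opposite (every position exactly on a
  bucket edge, splitting each peak 50/50) was explicitly avoided.
* Abundances preserve the plasma hierarchy (lipid envelopes and glucose
  largest, then lactate, then amino acids) but compress the true
  dynamic range, so that every modelled discriminator carries a
  quantifiable resonance; threonine sits at the top of its physiological
  range and its reporting resonance is the 3.585-ppm αCH, because its
  CH₃ doublet is buried under lactate — exactly as in real plasma
  spectra. Under Pareto scaling VIP weights buckets by √sd, so a
  low-abundance resolved resonance is otherwise invisible at VIP > 2
  regardless of effect size.
* The lactate 1.33 line is the dominant sharp peak of the referencing
  window (roof-effect doublet asymmetry, CPMG-attenuated broad lipid
  envelopes); window-maximum referencing then misfires in well under 1%
  of samples.

Not modelled: J-coupling quantum mechanics and multiplet fine structure,
relaxation filtering, baseline and phase errors, macromolecule baselines,
and correlated (e.g. lipoprotein-subclass) concentration structure.
Passing tests therefore show that the pipeline recovers a planted,
well-posed signal under realistic spectral geometry and class imbalance;
they do not certify performance on real patient spectra, where overlap,
baseline artefacts and covariate structure are harsher.

## Problem sizes used in the checked experiments

Parameter recovery runs 20 seeds of the full pipeline at n = 284
(prevalence 0.082, split 192/92 by referral order): each injected
discriminator's principal bucket reaches VIP > 2 in ≥ 80% of seeds and
the test-set AUC exceeds 0.8 in ≥ 80% of seeds. Null calibration runs 20
no-effect cohorts (n = 192) with 2×10-fold CV against 20-permutation
nulls. Type-I control of the KS comparison is measured on 100 no-effect
cohorts (n = 96, 8 positives) over a restricted 0.5–3.0 ppm bucket
region. The acceptance script replays one seeded study (10×10-fold CV,
20 permutations) plus 10 null cohorts in about two minutes on one CPU.

## Known limitations

* The discriminant is linear with one predictive component; strongly
  nonlinear class structure is out of scope (as is multi-class OPLS-DA
  and missing-value handling beyond rejection).
* KS comparison of a real CV distribution (conditional on the one
  observed label assignment) against a permutation null (marginal over
  assignments) becomes anticonservative as the number of repeats grows:
  with enough models per cohort, tiny conditional deviations are always
  detectable. The desk-scale defaults (2–10 repeats against ≥ 20
  permutations) are within the regime where the measured false-positive
  rate is ≤ 10%.
* Window-maximum referencing assumes a dominant lactate line; spectra
  where lactate is not the window maximum would be misreferenced by up
  to ±0.1 ppm and should be caught by upstream QC.
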