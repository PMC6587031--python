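# Methods

`seqradiomics` implements a multiparametric breast-MRI radiomics analysis
for immunohistochemistry (IHC) subtyping — Luminal A, Luminal B,
HER2-positive and triple-negative (TN) — from dynamic contrast-enhanced
(DCE) and diffusion-weighted (DWI) series. This note records the models,
the pinned numerical conventions, and the choices made where the design was
genuinely open.

## Feature catalog

Each subject contributes nine co-registered acquisitions: six DCE phases
(one pre-contrast, five post-contrast) and three DWI b-values
(50/400/800 s/mm²), with one whole-tumor mask per modality that is
propagated identically to every volume of its series (the series are
co-registered by acquisition; no resampling is performed, and DCE and DWI
grids are never pooled at the image level, only at the feature-table
level).

The catalog has 2,498 columns:

| group | count | definition |
|---|---|---|
| DCE shape | 14 | mesh/axis shape descriptors of the mask on the first post-contrast DCE volume |
| DCE texture | 92 × 6 = 552 | texture features per DCE phase |
| DCE sequential | 92 × 10 = 920 | trajectory statistics across the 6 phases |
| DWI texture | 92 × 3 = 276 | texture features per b-value |
| DWI sequential | 92 × 8 = 736 | trajectory statistics across the 3 b-values |

The 92 texture features are pinned in a frozen manifest
(`seqradiomics.manifest`): first-order 18, GLCM 23, GLRLM 16, GLSZM 16,
GLDM 14, NGTDM 5. Conventions: intensities are discretized to a fixed 32
gray levels between the ROI minimum and maximum (making all matrix-family
features invariant to affine intensity rescaling); GLCM and GLRLM use the
13 unique 3D distance-1 offsets with per-offset symmetric/normalized
matrices averaged across offsets; GLSZM zones, GLDM dependencies (tolerance
α = 0, dependence size = 1 + dependent 26-neighbors) and NGTDM
neighborhoods are 26-connected. Degenerate ROIs return defined limits
(e.g. GLCM contrast 0 and correlation 1 on a single gray level; NGTDM
coarseness capped at 10⁶). Shape surfaces are 0.5 level-set meshes of a
Gaussian-smoothed (σ = 1 voxel) mask indicator, which removes most
voxelization bias from the surface-area estimate; structures too thin to
survive smoothing fall back to the raw binary mesh. Non-finite feature
values are imputed to 0 with a logged warning (0 is the neutral value after
z-scoring).

## Sequential (trajectory) statistics

For every base texture feature, its per-subject values across an
acquisition axis form a trajectory `x ∈ R^T` (T = 6 for DCE, 3 for DWI).

Per-subject statistics (population 1/T moments — a trajectory is a fixed
short sequence, not a sample): mean, variance, skewness `m₃/m₂^{3/2}`,
kurtosis `m₄/m₂²` (both 0 when m₂ = 0), energy `Σx²`, entropy
`−Σ pₜ log₂ pₜ` with `pₜ = |xₜ|/Σ|xₛ|` (0 for an all-zero trajectory).

Cohort-interactive statistics compare subject i with the remainder:

* **Kendall tau-b** — mean over j ≠ i of the tie-corrected rank correlation
  `tau_b(xⁱ, xʲ) = (C − D)/√((n₀−n₁)(n₀−n₂))`, 0 when a denominator factor
  vanishes;
* **conservation** — mean over j ≠ i of the fraction of the T−1 successive
  steps whose difference signs agree;
* **stability** — `1/(1 + RMSD(x̃ⁱ, c̃))` with x̃ the min–max-normalized
  trajectory and c̃ the mean of the other subjects' normalized
  trajectories;
* **dispersion** — `√((1/T) Σₜ z²ₜ)` with z the per-time-point full-cohort
  z-score (population sd; 0 where the sd is 0), so the cohort mean of
  dispersion² is exactly 1 at every time point with nonzero spread.

These four definitions are this package's pinned interpretations of
"interactive information between the current subject and the remainder";
each lives behind its own function so an alternative convention can be
swapped in. Kurtosis and entropy are dropped for DWI (three points are too
few), giving 8 instead of 10 statistics; skewness is retained at T = 3
because exactly two statistics must be dropped to reach the 8-statistic
set. The assembly path uses vectorized cohort-level identities (sign-vector
form of tau-b, one-hot step-sign agreement) that the test suite verifies
against the per-subject definitions to 1e-12.

## Two-stage feature selection

**Coarse stage.** Each feature is mapped to (p, e): p from one-way ANOVA
(four-class) or a pooled two-sample t-test (TN vs non-TN; constant columns
get p = 1), e the stratified 5-fold error of a univariate Gaussian
linear-discriminant classifier (pooled within-class variance, denominator
n − K, log priors from the training folds; vectorized over all columns at
once). A feature is kept iff `(p/a)² + (e/b)² < 1` (strict). Defaults
(a, b) = (0.6, 0.85) four-class and (0.54, 0.76) binary; alternatively an
exhaustive 0.01-step grid search picks (a, b) minimizing the distance of
the retained count to half the catalog, ties broken by smaller ellipse
area then smaller a. No multiple-testing correction is applied: the raw
p-value is a coordinate of the gate, not an inference.

**Fine stage.** Accepted features are z-scored and ranked by three
regularized linear models — lasso (ℓ1), ridge (ℓ2) and elastic net
(mixing 0.5) — with logistic loss (multinomial for four classes) and
penalty strength chosen per method by internal stratified 5-fold CV
minimizing deviance (mean log-loss; accuracy plateaus produce degenerate
ties toward maximal sparsity). Importance is the magnitude of the
standardized coefficient (summed |coef| over classes); ties share the mean
rank. The three ranks are summed; the 40 lowest fused scores are kept; a
greedy scan in fused-score order then removes any feature whose absolute
Pearson correlation with an already-kept feature exceeds 0.4, stopping at
20 (four-class) or 8 (binary) features. The original analysis removed
correlated features manually; the greedy scan is a deterministic,
auditable automation of that step and may keep fewer than the requested
count when the candidate list is exhausted (logged).

Selection is run once on the full cohort before CV evaluation, mirroring
the modeled analysis sequence; `nested=True` re-fits the selector inside
every training fold to quantify the selection-leakage optimism of that
sequence.

**Rad-score.** A per-subject linear combination of the final standardized
features: the logistic linear predictor with TN as the positive class
(binary) or the first linear-discriminant axis (four-class).

## Classifier comparison harness

Twenty pinned presets (trees 3, discriminant 2, SVM 6, KNN 4, ensembles 5),
each wrapped with a fold-local standardizer. Pinned hyperparameters:
fine/medium/coarse trees at 100/20/4 maximum splits (Gini); SVM box
constraint 1, polynomial degrees 2/3, Gaussian kernel scales √P/4, √P, 4√P;
KNN k = 1/10/100 (capped at n_train − 1) plus squared-inverse-distance
weighted k = 10; ensembles of 30 learners, subspace dimension ⌈P/2⌉ for
subspace discriminant/KNN, AdaBoost and RUSBoost on 20-split trees at
learning rate 0.1, bagged trees unpruned. RUSBoost (boosting with
per-iteration class-balanced random undersampling and SAMME weight
updates) is implemented in-package as an sklearn-compatible estimator.

Evaluation is stratified 5-fold CV repeated for 10 rounds with
round-specific seeds; per round the accuracy is pooled correct/total over
the folds, and the reported number is the mean over rounds (for a
134-subject cohort the pooled-vs-fold-mean distinction is below one
subject of rounding). Accuracy is the headline metric; confusion matrices
of the last round are kept for diagnostics.

## Synthetic data

Two generators make every stage testable without patient data.

**Phantom images.** An ellipsoidal lesion (default semi-axes 9×8×7 mm,
matching the study's 18–25 mm median tumor diameters) in a uniform
background (level 100, Gaussian noise sd 5). Subtype signal enters three
ways: (i) DCE lesion mean follows a piecewise-linear enhancement curve —
wash-in to a subtype-specific peak phase, then washout — with Luminal A
slow/persistent (slope 0.12/phase, peak 5) through TN fast/washing-out
(0.45/phase, peak 1, washout 0.12); (ii) DWI lesion signal is
`S0·exp(−b·ADC)` voxelwise with ADC ~ N(mean, sd²) truncated positive,
means 1.10/0.95/0.90/0.80 ×10⁻³ mm²/s and heterogeneity sds
0.08/0.12/0.15/0.25 ×10⁻³ (TN lowest ADC and most heterogeneous,
reflecting necrosis); (iii) intra-lesion texture is a unit-variance
Gaussian random field with subtype-specific correlation length
(0.5/1.0/1.5/2.5 mm), giving subtypes distinct co-occurrence signatures.
Default cohort prevalence is 26:68:18:22 (n = 134). Per-subject seeds
derive from the cohort seed via `SeedSequence`, so cohorts are
deterministic and subjects independent. The phantoms deliberately omit
coil profiles, EPI distortion, fat-saturation artifacts, partial-volume
boundaries and inter-acquisition motion — passing tests demonstrate the
pipeline's statistical machinery, not clinical performance.

**Direct feature tables.** Gaussian columns with unit noise variance;
planted informative columns receive class-conditional mean offsets drawn
once per feature across classes, centered and scaled to a standardized
effect of 0.6 sd (default); optional correlated blocks share a latent
factor at a stated correlation. The 0.6 sd default is a deliberate
moderate-to-large subtype effect: with four classes only three independent
label contrasts exist, so any set of many strongly informative features is
mutually correlated *through the label*; beyond roughly 1 sd that induced
correlation crosses the 0.4 pruning threshold and the pruning stage
correctly removes planted features. At 0.6 sd the induced correlation
stays structurally below the threshold while the planted signal remains
unambiguous (ANOVA p < 1e-6 at n = 134).

On image phantoms the subtype signal is strong and shared across many
catalog columns, so after pruning at |r| ≤ 0.4 the final set is often far
smaller than the requested 20 — expected, logged, and harmless to the
comparison harness.

## Problem sizes and numerical conventions

Test and acceptance runs use a 32³ grid at 1.25 mm spacing with a 7×6×5 mm
lesion (a few hundred ROI voxels) and a 40-subject cohort at the study's
prevalence ratios; the planted-recovery simulation uses 50 seeds of
134 × 500 tables. These sizes were chosen so a full run completes in
minutes on one CPU while every catalog count and statistical property is
exercised at full width.

Numerical conventions collected in one place: strict inequality at the
ellipse boundary; tie-breaks (tuner: area then a; fused scores: stable
sort by column order; C grid: first minimum); degenerate denominators
return 0 unless a different limit is defined; feature tables round-trip
through CSV at %.17g; all stochastic stages consume explicit integer
seeds and are bit-reproducible.

## Known limitations

* The 92-feature identity and the four cohort-interactive definitions are
  pinned package conventions; other radiomics toolchains order and define
  features differently, so absolute feature values are comparable only
  within this package.
* Selection before CV (the default, mirroring the modeled analysis)
  leaks information; use `nested=True` for honest error estimates.
* QDA with near-singular class covariances relies on a small
  regularization (reg_param 1e-3); with more features than class members
  its accuracy is essentially that of a regularized approximation.
* The phantom generator's subtype separability is far cleaner than
  clinical data; harness accuracies on phantoms say nothing about
  patient-level performance.
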