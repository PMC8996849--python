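# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `salrad`, and what the synthetic-data experiments do and
do not demonstrate.

## Image preprocessing

PET activity concentration (Bq/mL) is converted to body-weight SUV,

SUV = activity × body weight [g] / (injected dose × 2^(−Δt / T½)),

i.e. the injected dose is decay-corrected from injection to acquisition and
tissue density is taken as 1 g/mL. Body-weight normalization was chosen
over lean-body-mass or BSA variants as the most common convention; all SUV
values are clamped at zero. CT is clipped to the (−200, 300) HU
soft-tissue window to suppress air and bone before any saliency or feature
computation. Images and masks are cropped to the minimal axis-aligned
tumor bounding box (margin 0 by default, configurable) and resampled to
1 mm isotropic — trilinear for images, nearest-neighbor for masks, output
shape = round-half-up(extent / target). Arrays are indexed (x, y, z) in
header order, 0-based. PET and CT are assumed pre-registered on a common
grid; no registration is performed.

## Context-aware saliency

The saliency model is a local–global patch-dissimilarity scheme applied
per axial slice of the cropped box:

1. **Intensity scale.** Each slice is min–max normalized to [0, 1]
   (a constant slice maps to zeros), so patch intensity distances are
   comparable across patients and modalities.
2. **Dissimilarity.** d(p_i, p_j) = ‖p_i − p_j‖ / (1 + c·‖x_i − x_j‖),
   with c = 3 and pixel positions divided by the slice diagonal — this
   makes c scale-free with respect to crop size.
3. **Multi-scale comparison.** Query patches are taken densely (stride 1,
   fully contained) from the slice rescaled by r ∈ {1, 0.8, 0.5, 0.3}
   with patch edges 7, 5, 3, 3; candidate patches come from that image
   further rescaled by {1, ½, ¼}, compared at the same pixel patch size.
   Candidates are pooled across the three relative scales and the K = 64
   smallest dissimilarities (excluding the query patch itself) are
   averaged: S^r = 1 − exp(−mean d). When fewer than K candidates exist
   the mean runs over all of them; a scale whose patch no longer fits is
   skipped with a warning. Border pixels inherit the nearest computed
   value; coarse-scale maps are upsampled bilinearly.
4. **Foci weighting.** Per-scale maps are averaged (N = 4) and each pixel
   is attenuated by its diagonal-normalized Euclidean distance to the
   nearest attention focus: S = S̄·(1 − d_foci). Foci are pixels with
   S̄ > 0.8; when no pixel reaches 0.8 — the common case for the raw
   1 − exp(−·) values, whose observed maxima sit near 0.6–0.7 — the argmax
   pixel(s) serve as foci, which keeps the weighting defined and preserves
   the map's ordering.

Saliency values are kept on their natural scale, which guarantees
S ∈ [0, 1) with constant inputs mapping to exactly 0. A final min–max
normalization of the map was prototyped and rejected: it attains exactly
1.0 at the foci (breaking the half-open range contract) and did not
improve sub-region detection on phantoms. All parameters are the published
defaults; nothing is tuned.

Two open conventions were resolved as follows: saliency maps are kept
**per modality** (PET and CT each get their own map and sub-regions), and
foci/d_foci are computed **per slice**, matching the slice-wise map
generation (a per-volume 3D variant was measured and was no better).

Sub-regions split the tumor mask at S > 0.5 (highSal) vs S ≤ 0.5 (lowSal);
a sub-region under 2 voxels is flagged unusable rather than extracted.
SalxImg multiplies the [0, 1]-normalized volume by the map; FusedImg sums
the PET and CT SalxImg volumes on normalized intensities so HU and SUV
units never mix.

## Radiomics features

Intensities are discretized with a fixed bin number (64):
level = min(n, ⌊n·(x − min)/(max − min)⌋ + 1), constant ROIs → level 1.
The default configuration computes ≈144 features in nine families:
morphology (voxel volume, mesh surface area, sphericity, maximum 3D
diameter, PCA axis lengths, elongation, flatness, …), intensity
statistics, intensity histogram, and the 3D texture families GLCM, GLRLM,
GLSZM, GLDZM, NGTDM, NGLDM. Texture matrices merge the 13 unique 3D
directions into a single matrix before feature computation
(merged-direction aggregation, stated here because conventions differ);
zones use 26-connectivity; GLDZM distances are city-block to the ROI edge
(edge voxels = 1). Degenerate single-level ROIs yield contrast 0 and
correlation 1 by convention. Reference feature counts in the several
hundreds are reached by also computing 2D/2.5D aggregation variants of
every texture family; those variants triple the surface without adding
information the 3D families do not carry on isotropic grids, so this
package deliberately ships the 3D set only — feature *count* parity with
any particular reference tool is a non-goal.

Masks below 2 voxels produce an all-NaN vector flagged `missing`, keeping
patient × feature tables aligned.

## Reproducibility screening and redundancy

Inter-observer reproducibility uses the two-way random-effects,
single-rater, absolute-agreement ICC; intra-observer uses the two-way
mixed-effects single-measurement form. Both share the ANOVA equation

ICC = (MSR − MSE) / (MSR + (k − 1)·MSE + (k/n)·(MSC − MSE)),

and may be negative for noise features. Features need ICC > 0.8 on both
to survive; fused-image features additionally require reproducibility on
both source modalities. Redundancy pruning walks a performance ranking
greedily and keeps a feature iff |Spearman ρ| ≤ 0.8 against everything
already kept (the redundancy rule is a package choice; constants are
skipped outright).

## ComBat harmonization

The parametric empirical-Bayes variant: per feature, batch means and
covariate effects are fit by least squares; data are standardized by the
size-weighted grand intercept, covariate effects and pooled residual SD;
per-batch location γ̂ and scale δ̂² estimates are shrunk toward
across-feature normal / inverse-gamma priors by iterated posterior-mean
updates (tolerance 1e-4, error on non-convergence); adjusted values
restore the grand mean and covariate effects. A single batch is an
identity pass-through. Categorical covariates are one-hot encoded with
the first level dropped; covariates constant overall or perfectly
confounded with batch are dropped with a warning. The implementation
matches Bioconductor `sva::ComBat` to ~1e-5 on shared inputs (tested).

Three batch divisions mirror multi-center acquisition variability:
center, manufacturer, and voxel size (PET in-plane-resolution bins
1.9–3.0 / 3.1–3.5 / 3.6–4.5 / 4.6–5.5 mm; CT slice-thickness bins 1.5 /
2.0 / 2.1–2.6 / 2.7–3.0 / 3.1–3.3 / 3.4–5.0 mm; out-of-range values clamp
to the nearest bin). Harmonization is fit on the combined cohort, which
reflects how multi-center radiomics studies commonly apply ComBat but is
a known train/test-leakage caveat for strict external validation.

Note on residuals: EB shrinkage deliberately leaves part of each
feature's *sampling* deviation in place, so post-harmonization per-feature
between-batch differences equal sampling noise (≈√(2/n)·SD), not zero;
recovery is judged on across-feature aggregates.

## Survival and model construction

Harrell's C counts concordant permissible pairs with ½ credit for score
ties; pairs with tied times and two events are not permissible. The Cox
fitter maximizes the Efron-tie-corrected partial likelihood by damped
Newton iterations (internal covariate standardization, step halving for
guaranteed ascent, gradient max-norm < 1e-8); a converged standardized
|β| > 10 is reported as separation rather than returned. Efron was chosen
over Breslow as the more accurate default; one consequence is that
duplicating all rows changes estimates slightly (ties are created), so
the weight-doubling invariance holds only approximately.

Outcome-model construction follows the multi-endpoint recipe: per-feature
univariate Cox C-indices for RFS/MFS/OS/DFS on training, ranking by mean,
top-20 non-redundant screen, then 19 nested DFS models (first k features,
k = 2..20) fit on training. Each model is scored by the mean of eight
C-indices — the four training endpoints (including the DFS index it was
fit on) and the four validation endpoints — and the best mean wins;
models that fail to converge are skipped with a warning. The stepwise
direction is forward-only in screened order; no backward elimination.
The resulting linear predictor (Rad_Ocm) is dichotomized at the *training*
median for Kaplan–Meier / log-rank reporting (lifelines) with a hazard
ratio from a univariate Cox fit on the group indicator; CIs are
100-replicate percentile bootstraps over patients, redrawing replicates
on which a metric is undefined (≤10 retries).

The HPV arm sorts features by univariate AUC, prunes redundancy, fits
logistic models (statsmodels) on the top k = 2..20, and selects by
rank(−AUC) + rank(BIC), BIC = −2ℓ + p·ln n; fewer than 5 minority-class
cases is an error. "Integration" of Rad_Ocm and Rad_HPV is not uniquely
defined by the procedure it follows; this package refits a bivariate DFS
Cox model on the two scores — the simplest faithful combination — and
falls back to Rad_Ocm alone under near-collinearity (|ρ| > 0.99) or a
degenerate fit. Train/validation splits are stratified on DFS event
status with a seeded RNG. Patients missing an endpoint are dropped for
that endpoint only.

The localization statistic is ‖argmax S − centroid(mask)‖ divided by the
farthest in-mask voxel's distance to the centroid, in physical mm; a
single-voxel mask returns 0.

## Synthetic data

**Phantoms** are 64×64×16 voxel (1 mm) PET/CT pairs: an ellipsoid lesion
(radii 14/11/6 voxels; SUV-like level 4 over background 1; HU-like 50
over 20) containing an offset sub-lesion habitat (radii 5/4/3, ≈5% of
tumor volume) whose intensity is the lesion level × contrast (default 2)
on both modalities, plus Gaussian noise (PET σ = 0.2 ≈ 5% of the lesion
level, CT σ = 5 HU) — a smoothed FDG-avid tumor with one hypermetabolic
habitat. The pipeline's per-patient phantoms jitter radii, offset and
contrast by ±15–20% so cohort members differ.

**Cohorts** draw features x = μ_j + covariate effects + γ_b + δ_b·ε with
ε ~ N(0, 1); the prognostic signal η = Σβ·ε rides on the batch-free noise
component, so harmonization can in principle restore it. β is scaled so
the population concordance of η hits a target (default 0.75) via the
closed-form pairwise-ordering probability E[sigmoid(|Δη|)] solved by
quadrature + bisection. Survival times are Weibull (shape 1.2, scale 60
months) with rate ∝ exp(η) for three component endpoints (recurrence,
metastasis, death; DFS = first of the three), under shared independent
uniform censoring whose upper bound is bisected to hit the target
censoring fraction (default 0.3). HPV labels are Bernoulli(sigmoid(x·β))
on two designated features.

What the phantoms do **not** emulate: PET reconstruction physics (PSF,
Poisson counts, reconstruction smoothing), anatomical context outside the
tumor box, registration error, correlated multi-habitat architecture, and
realistic feature covariance (simulated features are independent given
batch and covariates). Passing tests therefore demonstrate the
*machinery* — estimator correctness, batch-effect removal, selection
recovery, determinism — not clinical performance; C-indices on simulated
cohorts say nothing about real HNC cohorts.

## Numerical conventions and sizes

- Saliency brute-force oracle agreement is exact to ~1e-16; the
  vectorized path is the production one.
- Pipeline runs use 20-patient phantom cohorts (48×48×12 grids) with
  three segmentation variants (one boundary-jittered re-segmentation per
  "observer") — sizes chosen so a full run completes in well under a
  minute while still fitting one model per image type.
- The model-selection experiment uses 500/100/200 train/val/test with 100
  features, 3 prognostic; the HPV experiment 100 replicates of n=150 with
  2 informative / 18 noise features; ComBat recovery 3 batches × 200.
- All randomness flows from explicit seeds; identical configurations
  reproduce identical artifact hashes (manifest-verified).

## Known limitations

- Saliency is 2D slice-wise; a 3D patch formulation would avoid
  inter-slice inconsistency but is out of scope.
- With the default patch sizes, sub-region boundaries are resolved only
  to ~patch-radius precision: on phantoms the 0.5-threshold high-saliency
  region detects a planted contrast-2 habitat in 50/50 cases by mean
  saliency but overlaps it with median Dice ≈ 0.5 when the habitat radius
  (4–5 voxels) is comparable to the 7-voxel patch edge. Larger habitats
  are localized proportionally better.
- Exact feature-count parity with reference radiomics tools is not
  attempted (3D families only).
- ComBat is fit jointly across cohorts (leakage caveat above); M-ComBat
  style reference-batch alignment is not implemented.
- The Cox fitter targets well-posed problems; heavy separation raises
  rather than regularizing (no ridge fallback by design).
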