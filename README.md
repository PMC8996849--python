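# salrad — context-aware saliency-guided PET/CT radiomics

`salrad` implements a saliency-guided radiomics workflow for paired
¹⁸F-FDG-PET/CT tumor volumes, aimed at outcome and HPV-status prediction in
head-and-neck cancer and at tumor sub-region (habitat) analysis in general.
Not every tumor voxel contributes equally to prognosis; a visual-attention
model can score each region's *distinctiveness* and steer feature
extraction toward the regions that carry signal. The package provides the
whole chain — saliency-derived image types, IBSI-style feature extraction
with reproducibility screening, multi-center ComBat harmonization, and a
multi-endpoint model-construction procedure — and ships a synthetic-data
module (phantoms and simulated cohorts) so the full pipeline runs and is
testable without any clinical download.

## The model

**Context-aware saliency.** For a pixel *i* with image patch *p<sub>i</sub>*,
patch dissimilarity trades intensity difference against spatial proximity:

```
d(p_i, p_j) = d_intensity(p_i, p_j) / (1 + c · d_position(p_i, p_j)),   c = 3
```

with Euclidean distances and positions normalized by the slice diagonal.
A pixel is salient when even its K = 64 most similar patches are far away:

```
S_i^r = 1 − exp( −(1/K) Σ_k d(p_i^r, p_k^s) )
```

computed at four image scales r ∈ {1, 0.8, 0.5, 0.3} (patch edges 7/5/3/3,
candidate patches at relative scales {1, ½, ¼}), averaged into S̄_i, and
attenuated by the distance to the nearest attention focus (pixels with
S̄ > 0.8): `S_i = S̄_i · (1 − d_foci(i))`. Maps are computed per axial slice
of the tumor bounding box, on SUV-converted PET and (−200, 300)-HU-windowed
CT resampled to 1 mm isotropic.

**Six image types** feed radiomics extraction: the original image (Origin),
the saliency map (SalMap), the high-/low-saliency tumor sub-regions at a
0.5 threshold (highSal/lowSal), the saliency-weighted image (SalxImg), and
the sum of the weighted, normalized PET and CT images (FusedImg).

**Features and screening.** Intensities are discretized to 64 bins
(fixed bin number); morphology, intensity statistics, intensity histogram,
GLCM, GLRLM, GLSZM, GLDZM, NGTDM and NGLDM families are computed per IBSI
definitions with 3D merged-direction aggregation. Features must reach
ICC > 0.8 (two-way ANOVA, single-rater, absolute agreement) for both
inter- and intra-observer segmentation variation; fused-image features are
kept only when reproducible on both PET and CT.

**Harmonization.** Parametric empirical-Bayes ComBat removes per-batch
location/scale effects under three batch divisions — center, scanner
manufacturer, or voxel-size group (PET in-plane-resolution bins, CT
slice-thickness bins) — while protecting clinical covariates.

**Model construction.** Features are ranked by their mean univariate Cox
C-index over four endpoints (RFS, MFS, OS, DFS) and pruned to the top 20
non-redundant (|Spearman ρ| ≤ 0.8). A DFS Cox model grows by stepwise
addition (19 nested models, k = 2..20); the winner maximizes the mean of
eight C-indices (four training endpoints + four validation endpoints), and
its linear predictor is the outcome score **Rad_Ocm**, dichotomized at the
training median for Kaplan–Meier / log-rank reporting with 100-bootstrap
CIs. The HPV arm ranks features by AUC, fits logistic models on the top
k = 2..20, and selects by summed ranks of descending AUC and ascending
BIC (**Rad_HPV**); a bivariate Cox refit on both scores gives
**Rad_Ocm_HPV**. A localization statistic reports the normalized distance
(0 = centroid, 1 = farthest edge) between the saliency peak and the tumor
centroid.

## Worked example

Construct an outcome score on a simulated multi-center cohort with three
planted prognostic features among 100 (generative concordance 0.75):

```python
import numpy as np
from salrad import (CohortSpec, simulate_cohort, univariate_screen,
                    stepwise_outcome_model, c_index, km_logrank)

cohort = simulate_cohort(CohortSpec(n_patients=800, n_features=100,
                                    n_prognostic=3, target_cindex=0.75, seed=11))
feats, surv = cohort["features"], cohort["survival"]
idx = feats.index
train, val, test = idx[:500], idx[500:600], idx[600:]

selected, report = univariate_screen(feats.loc[train], surv.loc[train])
score = stepwise_outcome_model(selected, feats.loc[train], surv.loc[train],
                               feats.loc[val], surv.loc[val])
s_test = score.predict(feats.loc[test])
for ep in ("rfs", "mfs", "os", "dfs"):
    c = c_index(surv.loc[test, f"{ep}_time"], surv.loc[test, f"{ep}_event"], s_test)
    print(f"test C-index {ep.upper()}: {c:.3f}")
```

Printed output:

```
screened candidates: 20 (best mean C-index 0.659)
stepwise models evaluated: 19
selected Rad_Ocm features: ['f042', 'f032', 'f077', 'f062']
planted prognostic features: ['f077', 'f032', 'f042']
test C-index RFS: 0.788
test C-index MFS: 0.782
test C-index OS: 0.790
test C-index DFS: 0.767
DFS risk groups: HR=5.46, log-rank p=0.0000
```

The procedure evaluated exactly 19 stepwise models, recovered all three
planted prognostic features (plus one spurious one), and the resulting
score generalizes to the held-out test third at roughly the generative
concordance; the training-median split separates test-cohort risk groups
with a hazard ratio of 5.5.

The same stages run from the shell:

```bash
salrad simulate phantom --seed 3 --out-dir demo/
salrad saliency --pet demo/pet.nii.gz --ct demo/ct.nii.gz --mask demo/mask.nii.gz --out-dir demo/sal
salrad features --pet demo/pet.nii.gz --ct demo/ct.nii.gz --mask demo/mask.nii.gz --out demo/features.csv
salrad run-all --seed 3 --n 20 --out-dir demo/run    # full phantom-cohort pipeline
```

## Layout

| module | contents |
| --- | --- |
| `salrad.volume_io` | NIfTI I/O, SUV conversion, HU windowing, crop, resample |
| `salrad.saliency` | context-aware saliency maps and the six image types |
| `salrad.features` / `salrad.texture` | IBSI-style feature extraction |
| `salrad.reproducibility` | ICC screening, redundancy pruning |
| `salrad.harmonize` | parametric EB ComBat, batch-division strategies |
| `salrad.survival` / `salrad.modeling` | C-index, Cox, KM/log-rank, bootstrap, score construction |
| `salrad.synthetic` | phantoms and simulated multi-center cohorts |
| `salrad.pipeline` / `salrad.cli` | orchestration, manifests, `salrad` CLI |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
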