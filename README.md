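# emorsa

Representational-geometry analysis of emotion concepts and their neural
signatures.

People differ in how they carve up the emotion domain: how related they judge
words like "yelling" or "sweating" to be to *anger*, *fear*, or *sadness*.
`emorsa` implements a full pipeline for asking whether such idiosyncratic
**conceptual knowledge** of emotions is mirrored in the **representational
geometry** of brain activity during facial and vocal emotion perception:

1. **Conceptual RDMs** (`emorsa.concept`) — from a subject's 7 × 40
   emotion-by-word rating matrix, the dissimilarity between emotions *i* and
   *j* is the Pearson correlation distance of their rating vectors,
   `d(i, j) = 1 − r(x_i, x_j)`, giving a symmetric 7 × 7 representational
   dissimilarity matrix (RDM). Group averaging, Kruskal nonmetric MDS
   (classical-scaling start, SMACOF majorization with isotonic regression)
   and Ward hierarchical clustering summarize the geometry.
2. **Behavioral confusions** (`emorsa.behavior`) — an emotion-categorization
   confusion matrix is transformed to dissimilarities
   (`max off-diagonal − count`) and its z-scored upper triangle is correlated
   with the conceptual RDM (21 pairs, so *r* is reported on 19 df).
3. **Single-trial betas** (`emorsa.singletrial`) — Least-Squares-Separate
   (LSS): one GLM per trial with the target trial in one
   HRF-convolved boxcar regressor and all remaining trials collapsed into
   another, plus nuisance regressors, a 128-s discrete-cosine high-pass set
   and an intercept; ordinary least squares, one beta volume per trial.
4. **Searchlight RSA** (`emorsa.searchlight`) — within every 4-mm-radius
   sphere, per-emotion mean beta patterns give a neural Pearson-distance RDM
   whose lower triangle is regressed (standardized OLS) on the conceptual
   RDM, optionally alongside low-level control RDMs (pitch from
   autocorrelation, precomputed image features; `emorsa.features`). The
   standardized coefficients are Fisher-transformed (`atanh`) and mapped to
   the sphere center.
5. **Group inference** (`emorsa.groupstats`) — one-sided one-sample *t* maps
   over subjects, threshold-free cluster enhancement (TFCE, `E = 0.5`,
   `H = 2`), and a sign-permutation max-statistic test for FWE-corrected
   *p*/z maps (display threshold z ≥ 1.65), plus a voxelwise
   repeated-measures F test and a minimum-statistic conjunction.
6. **Synthetic data** (`emorsa.synthdata`) — deterministic generators that
   plant known structure: rating matrices whose empirical RDM follows a
   target with between-subject jitter, confusion counts decreasing with
   conceptual distance, beta volumes carrying an emotion code in a chosen
   region, forward-modeled BOLD, and audio test tones. These make every
   stage testable end to end without any data download.

Estimator-style classes (`NonmetricMDS`, `LssGlm`, `SearchlightRsa`,
`SignPermutationTest`) follow scikit-learn conventions (`fit`, fitted
`*_` attributes, `get_params`); plain functions wrap them for one-off use.

## Worked example

```python
import numpy as np
from emorsa import synthdata as sd
from emorsa.concept import rdm_from_ratings, average_rdm, nonmetric_mds
from emorsa.behavior import confusion_to_dissimilarity, correlate_upper_triangles

world = sd.PlantedWorld(seed=1, idiosyncrasy_sd=0.1, noise_sd=0.5)
rdms = [rdm_from_ratings(sd.gen_subject_ratings(world, s)) for s in range(25)]
group = average_rdm(rdms)
print(group.round(2).iloc[:4, :4])
sol = nonmetric_mds(group)
print(f"MDS stress-1 = {sol.stress:.4f}")
cm = sd.gen_confusions(group, temperature=0.5, n_trials_per_emotion=200, seed=2)
r, df, p = correlate_upper_triangles(confusion_to_dissimilarity(cm), group)
print(f"confusion-dissimilarity vs conceptual RDM: r({df}) = {r:.2f}, p = {p:.2e}")
```

```
           angry  disgusted  fearful  happy
angry       0.00       0.35     0.31   0.79
disgusted   0.35       0.00     0.34   0.77
fearful     0.31       0.34     0.00   0.77
happy       0.79       0.77     0.77   0.00
MDS stress-1 = 0.0001
confusion-dissimilarity vs conceptual RDM: r(19) = 0.77, p = 4.93e-05
```

Negative emotions cluster (small mutual distances), happy sits far from all
of them, the 2-D MDS embedding is essentially perfect, and pairs that are
conceptually closer are confused more often, so the transformed confusion
matrix correlates positively with conceptual dissimilarity.

The imaging half, end to end on synthetic subjects with a planted 125-voxel
signal region (pattern-RDM correlation with each subject's conceptual RDM
calibrated to ≈ 0.5 at searchlight scale):

```python
from emorsa.searchlight import run_searchlight
from emorsa.groupstats import sign_permutation_test

grid = (12, 12, 12)
region = np.array([(x, y, z) for x in range(3, 8) for y in range(3, 8) for z in range(3, 8)])
world = sd.PlantedWorld(seed=1, idiosyncrasy_sd=0.1, noise_sd=2.0,
                        signal_region=region, grid_shape=grid)
maps = []
for s in range(20):
    srdm = sd.sample_subject_rdm(world, s)
    betas = sd.gen_beta_volumes(world, srdm, trials_per_emotion=10, subject_id=s)
    rsa = run_searchlight(betas, betas.trials["trial_type"], [world.target_rdm])
    maps.append(np.nan_to_num(rsa.coef_maps_[0]))
res = sign_permutation_test(maps, n_perm=1000, seed=3)
```

```
significant centers inside region: 100%
significant centers elsewhere:     2.81%
smallest corrected p:              0.0010
```

The sign-permutation TFCE test recovers every center of the planted region
while keeping corrected false positives rare elsewhere (the residual hits
sit on spheres that overlap the region's edge).

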