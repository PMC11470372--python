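# Methods notes

This note records the models, conventions and numerical choices behind
`emorsa`, in the spirit of a statistical software appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conceptual dissimilarity and its summaries

A subject's conceptual RDM is the Pearson correlation distance
`d(i, j) = 1 − r(x_i, x_j)` between the 40-word rating vectors of emotions
*i* and *j*; entries lie in [0, 2] with 0 meaning rating profiles identical
up to an increasing affine map. Constant rating rows make *r* undefined and
raise an error naming the emotion — substituting `r = 0` silently would bias
group averages.

**Nonmetric MDS.** `NonmetricMDS` embeds an RDM by minimizing Kruskal
stress-1 with iterative majorization (scikit-learn's SMACOF in nonmetric
mode) and isotonic-regression disparities (tied dissimilarities share a
disparity). Initialization is the classical Torgerson solution
(eigendecomposition of the double-centered squared-distance matrix), making
the fit deterministic. The loop stops at 300 iterations or when SMACOF's
normalized-stress improvement falls below `1e-9`; on the stress-1 scale this
realizes improvements well below `1e-6`, and exactly- or
monotonically-embeddable inputs reach stress-1 < `1e-4`/`1e-3`. The reported
`stress` is always stress-1, recomputed from the final configuration with an
independent isotonic fit. Axes are not interpreted (no claim about valence
or arousal is built in); only configurations are produced.

**Ward clustering.** `ward_clustering` follows the "Ward2" convention for
dissimilarity inputs: the Lance–Williams update runs on squared
dissimilarities and merge heights are square-rooted, which keeps heights
monotone non-decreasing. The convention is recorded in the output
(`convention` key) because the two Ward variants in circulation differ
exactly here. scipy's `linkage(..., method="ward")` implements this
recurrence; the test suite checks its heights against an independent
hand-rolled Lance–Williams implementation at `1e-10`.

## Confusion analysis

The group confusion matrix (rows = presented emotion, columns = response) is
transformed by `d(i, j) = max_offdiag(counts) − counts(i, j)` with the
diagonal zeroed and excluded, then the z-scored strict upper triangles of
the confusion-derived and conceptual matrices are Pearson-correlated
(21 pairs for 7 emotions, df = 19). Two deliberate points:

* The transform as defined makes frequently-confused (conceptually close)
  pairs *less* dissimilar, so the expected correlation with conceptual
  dissimilarity is *positive*. Prose glosses sometimes describe the
  transformed matrix as "larger = more confusion", which is the opposite of
  what the formula does; the formula is authoritative here and the
  documented behavior is what the code implements.
* The confusion matrix is left asymmetric and only its upper triangle is
  used (a `symmetrize` option averages `(d + dᵀ)/2` but is off by default).
  No per-participant confusion analysis is provided; counts are pooled.

## Single-trial estimation (LSS)

* **HRF**: difference of two gamma densities (shape 6 and 16 at unit scale,
  undershoot ratio 1/6), truncated at 32 s and peak-normalized; peak lands
  near 5 s. Regressors are built on a microtime grid `dt = TR/16`, convolved,
  then sampled at `(i + 0.5)·TR` (mid-TR reference). Any consistent choice
  passes the recovery tests; this one mirrors common practice.
* **Boxcars**: each trial's full epoch is modeled (12 s in the standard
  design via the events table's `duration`; `boxcar_duration` overrides,
  e.g. to model only the 3-s stimulus).
* **High-pass**: `floor(2·T·TR/cutoff)` orthonormal discrete-cosine columns
  with periods above the 128-s cutoff; the filter lives inside the design
  matrix, so anything in its span is absorbed exactly (asserted at `1e-8`).
* **Estimation**: plain OLS, no AR(1) prewhitening — the single-trial model
  is specified with filtering and nuisance regressors only, and unwhitened
  OLS keeps the estimator exactly testable against forward simulations.
  Rank-deficient designs fail loudly, naming the collinear columns.
* A known algebraic limit: with more than two trials and *unequal*
  amplitudes, the collapsed "other trials" regressor cannot represent the
  data even without noise, so LSS is exactly equal to the all-trials-separate
  GLM only when trials are far apart (disjoint HRF support) *and* the other
  trials share an amplitude, or when there are exactly two trials. The test
  suite uses those regimes for its `1e-6`/`1e-8` oracles and a noisy
  unequal-amplitude case at realistic tolerance.

## Searchlight RSA

* Sphere membership uses **world-space** distance via the affine's linear
  part, honoring anisotropic voxels; on an isotropic 3-mm grid a 4-mm radius
  keeps the center plus its six face neighbors (edge diagonals sit at
  √18 ≈ 4.24 mm). Centers with fewer than 3 in-mask members are dropped and
  recorded — a Pearson correlation across fewer voxels is degenerate.
* The neural RDM correlates per-emotion *mean* beta patterns (averaged over
  that emotion's single-trial estimates) across sphere voxels and subtracts
  from 1.
* The regression standardizes the response and each model's lower-triangle
  vector and fits OLS with an intercept. Standardization makes the
  single-model coefficient a Pearson correlation, so the Fisher transform
  (`atanh`) is well defined; unstandardized coefficients could exceed 1 and
  diverge. Exact fits are clipped at `1 − 1e-7` before `atanh`. Both the
  standardization and the intercept are exposed as flags. The triangle
  vectorization order (row-by-row over `i > j`) is frozen for
  bit-reproducibility; any consistent order is statistically equivalent.

## Group inference

* One-sided one-sample *t* against zero per voxel (interest is in positive
  conceptual-neural association); zero-variance voxels get `t = 0`.
* **TFCE** with the field-standard `E = 0.5`, `H = 2`, 26-connectivity, and
  `dh = observed_max/100`; all are configurable and recorded in the result's
  provenance. The same `dh` (an absolute step) is applied to the permuted
  maps so the enhancement is one fixed transform. Two backends (a
  numba flood-fill used in the permutation loops and a scipy.ndimage
  labeling reference) are cross-checked to `1e-10` in the tests; with
  `E = H = 0` and fine `dh` the transform reduces to the input map, and an
  isolated voxel of height *h* integrates to `h³/3`.
* **Sign-permutation test**: under the symmetric null each subject's map is
  flipped by an independent fair coin; `t` and TFCE are recomputed and the
  maximum over in-mask voxels recorded. "Sign-permutation with many
  iterations" is read as the standard one-sample sign-flipping scheme with
  random assignments; when `2ⁿ ≤ n_perm` the full 2ⁿ enumeration is used
  instead. Corrected `p(v) = (1 + #{max_perm ≥ obs(v)}) / (n_perm + 1)` —
  the +1 convention keeps `p ≥ 1/(n_perm+1) > 0` — and the z map
  `Φ⁻¹(1 − p)` is capped accordingly; the display/significance threshold is
  z ≥ 1.65 (p < .05, one-tailed). Max-statistic correction over the supplied
  mask is the permutation analogue of family-wise error control; no
  Gaussian-random-field cluster correction is provided, and the univariate
  path instead offers the simplified voxelwise repeated-measures F
  (`df = (6, 6(n−1))` for 7 conditions) plus the minimum-statistic
  conjunction (minimum map, and the AND of the two per-map corrected
  significance sets).

## Synthetic data: what is emulated, what is not

Generators plant exactly the structure the analysis assumes, which is what
makes the recovery tests informative — and bounds what they show:

* **Ratings**: emotion prototypes over words are drawn with *empirical*
  pairwise correlations equal to `1 − RDM` (rows are centered, whitened to
  unit sample covariance, then mixed with a square root of the target
  correlation matrix), then jittered per subject, noised, affine-mapped to
  mean 4 / sd 1.2 on the 1–7 scale, rounded half-up and clipped. The default
  group prototype RDM derives from a Gaussian similarity kernel over a 2-D
  valence/arousal-style layout (guaranteeing positive semidefiniteness);
  subject jitter (`idiosyncrasy_sd`, default 0.1) perturbs off-diagonals,
  after which the implied correlation matrix is projected back to PSD by
  eigenvalue clipping with diagonal renormalization. A target whose implied
  correlation matrix is not PSD is rejected outright.
* **Confusions**: row *i* is multinomial with probabilities
  `∝ exp(−d(i,j)/temperature)` — a planted monotone link that makes the
  confusion-vs-conceptual correlation positive by construction.
* **Betas**: within the signal region, per-emotion mean patterns are built
  with the same exact-correlation construction (possible whenever the region
  has more voxels than emotions; smaller regions fall back to an approximate
  mixture); each trial adds white Gaussian noise, and voxels outside the
  region are pure noise. Real BOLD has spatial autocorrelation, drift and
  motion structure that these volumes do not; passing tests therefore
  demonstrate correctness of the estimators, not robustness to scanner
  artifacts (an optional cosine drift exists only in the forward BOLD model
  used for filter tests).
* **Session/rating designs** use the task constants (4.5-s fixation, four
  3-s stimuli, 3-s fixation, 12-s block rest; 7 × 40 rating trials;
  4 × 7 × 4 + 2 = 114 session records). Catch trials are generated, flagged,
  and ignored by every analysis stage. Actor identity is an unconstrained
  label. The two catch trials attach after the final trial of two randomly
  chosen blocks.
* All generators are bit-reproducible: streams derive from
  `(world.seed, stream_tag, subject_id)`.

## Calibrations and problem sizes used by the checks

* The planted-signal recovery experiment uses 20 subjects, a 12×12×12
  3-mm grid with a 5×5×5 signal region, 10 trials per emotion, subject
  jitter 0.1 and `noise_sd = 2.0`. That noise level was calibrated once so
  that the correlation between a searchlight-scale (7-voxel) pattern RDM
  inside the region and the subject's RDM averages ≈ 0.5 — searchlight
  scale, not whole-region scale, because that is the effect size the moving
  sphere actually sees (pattern subsampling alone caps the sphere-level
  correlation near 0.7 even at zero noise). "Null" centers for the
  false-positive check are those whose spheres never touch the region:
  spheres overlapping the region's edge receive genuine signal and are not
  null.
* Family-wise error is measured on null datasets of 20 independent
  standard-Gaussian subject maps on a 10×10×10 grid: 500 datasets × 1,000
  permutations in `scripts/acceptance.py`, and 200 × 500 in the routine test
  suite, with the bound widened by two Monte-Carlo standard errors of the
  corresponding dataset count.

## Known limitations

* No preprocessing (motion correction, slice timing, normalization) — the
  pipeline starts from preprocessed 4-D series or beta volumes, and nuisance
  regressors are consumed as a ready-made table.
* No cross-validated distance estimators (e.g. crossnobis) or
  rank-correlation RSA; the regression RSA here is the correlation-distance
  OLS variant.
* The repeated-measures F omits sphericity correction; it is a simplified
  univariate path intended for mask construction and conjunction, not for
  publication-grade univariate inference.
* Pitch extraction assumes mono PCM input and clean periodicity; the 0.3
  voicing threshold, 75–500 Hz search range and frame/hop defaults are
  declared choices, inert for the clean synthetic fixtures and adjustable
  for real recordings. Image features (e.g. HMAX C2) are consumed as a
  precomputed table, never computed here.
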