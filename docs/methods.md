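# Methods

This note records the models, conventions and numerical choices behind
`fishrad`, and what the synthetic phantoms do and do not establish.

## Image model

A 2D optical image is a single-slice scalar volume: a pixel grid plus a
physical spacing triple (row, column, slice). Photographic formats
carry no pixel pitch, so spacing defaults to (1, 1, 1); every
spacing-dependent feature is then in pixel units, which is the only
self-consistent choice when the true geometry is unknown. RGB input is
collapsed to one gray channel with ITU-R BT.601 luma weights
(0.299, 0.587, 0.114) — the standard broadcast convention for
photographic JPEGs. Masks binarize at half the source dtype maximum, so
JPEG compression speckle near 0 or near the maximum does not flip
pixels.

## Preprocessing

Two downscaling pathways are implemented as genuinely different
numerical routes, because comparing them is part of the method:

* **resample** — physical-grid resampling via SimpleITK. Output grid =
  floor(input / f) per axis (minimum 1), in-plane spacing multiplied by
  f; image interpolated nearest-neighbor (default; "linear" available),
  masks always nearest-neighbor.
* **resize** — plain array rescale at import via scikit-image
  (bilinear image without anti-aliasing, nearest masks), with the same
  grid/spacing contract.

Both preserve the physical extent to within one output pixel pitch. A
mask that vanishes under downscaling raises a degenerate-mask error; at
the study level such regions are logged and skipped. This is not
hypothetical: a one-pixel-wide midline band survives factor-2.5
nearest-neighbor sampling only when an output sample happens to land on
it, so stability comparisons run on the surviving (specimen, region)
pairs and say so in the log.

Discretization uses a fixed **bin count** over the in-mask intensity
range (default 64; bin count 1 collapses every pixel to one level). The
alternative reading of a unit bin count — fixed **bin width** 1, which
preserves the original integer gray values — is implemented as
`discretization="width"`, so either interpretation of a "bin count 1"
protocol can be run; the literal single-bin reading is the default.
Z-score normalization (in-mask mean 0, population SD 1) is available
and off by default.

## The 107-feature set

14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM
features named `original_<class>_<Feature>`, IBSI-style. Conventions
that required a decision:

* **Single-slice extrusion.** The region is a solid of thickness t =
  slice spacing: VoxelVolume = N·pixel_area·t; MeshVolume = A_mesh·t
  with A_mesh the area inside the marching-squares contour at level 0.5
  (corners of a solid square are chamfered, so a 10×10 square has
  A_mesh = 99.5 and perimeter 36 + 2√2); SurfaceArea = 2·A_mesh + P·t.
  Axis lengths are 4√λ of the population covariance of in-mask pixel
  centres in physical coordinates; the slice axis contributes λ = 0,
  hence LeastAxisLength = Flatness = 0 identically on 2D data. Maximum
  diameters are the largest pairwise pixel-centre distances in the
  stated planes, with t as the slice-axis extent. At fixed thickness
  sphericity decreases with region area, so shape comparisons across
  sizes must area-match first.
* **Moments.** Variance and skewness are population (biased); kurtosis
  is non-excess (normal → 3). Entropy and Uniformity come from the
  discretized-level histogram, log base 2.
* **Texture aggregation.** GLCM and GLRLM are built per in-plane angle
  (4 unit offsets, distance 1) and the per-angle feature values are
  averaged; angles with no valid pair/run are dropped. GLSZM zones are
  8-connected; note that under 8-connectivity diagonal equal-level
  cells join, so e.g. a two-level checkerboard forms exactly two zones.
  GLDM uses the Chebyshev-1 neighborhood with tolerance α = 0 and
  dependence column d + 1 (a pixel with no dependent neighbor sits in
  column 1, making SmallDependenceEmphasis 1 for fully "independent"
  regions). NGTDM excludes pixels with no in-mask neighbor.
* **Degenerate conventions.** One gray level must never produce NaN:
  GLCM Correlation = 1, Imc1 = Imc2 = 0, MCC = 1, and NGTDM Coarseness
  is capped at 1e6 when its denominator vanishes. Entropies sum only
  over nonzero probabilities and single-level gray variances are set to
  an exact 0 — the ε-guarded formulas leave O(1e−16) residues that a
  relative-error analysis would amplify into astronomical percentages.
* Distances are fixed at 1 and only original-image (unfiltered)
  features are computed, which is what yields exactly 107 names.

Matrix construction is verified in the test suite against independent
brute-force enumeration (plain nested loops) on hundreds of random
grids, with exact count equality.

## Stability analysis

δ_ij = |v − v̂|/|v̂|·100 against the original-resolution reference; δ_i
averages over masks, M over features. The printed formula for δ is
signed in some descriptions; the magnitude is used here because means
of signed errors cancel. A reference value of exactly 0 with a nonzero
observation has no defined relative error: such entries are excluded
from the means and reported, rather than set to infinity. Features
whose δ_i exceeds 2% (configurable) are flagged. Condition pairs are
compared by win counts on δ_i and a classical two-tailed paired t-test
on the δ_i vectors (n = number of features); all-zero differences
report p = 1, constant nonzero differences report the infinite-t limit
p = 0. M is a mean and therefore dominated by its worst features —
NGTDM Coarseness, a reciprocal that hits its cap whenever downsampling
flattens a small region, can contribute percentages in the 1e7 range on
its own. The win counts and the paired test are the robust summaries;
M is reported because it is the conventional headline number.

## Selection and classification

* **PBC**: r_pb equals the Pearson correlation against the 0/1 label
  (verified to 1e−12 in tests); p from t = r√((n−2)/(1−r²)) on n−2 df.
  Selection keeps p < 0.05 ranked by |r|, capped at 2 by default (the
  cap is configurable; reported selections in this kind of study
  typically contain 1–2 features per analysis).
* **t-test**: Welch (unequal variances) rather than pooled, for
  robustness. No multiple-testing correction, by design.
* **ReliefF**: every sample is an anchor (m = n) so the weights are
  deterministic; min-max scaled features, k = 10 nearest hits/misses,
  miss contributions weighted by the prior odds of the other class.
* **LASSO**: L1 logistic path with the penalty chosen by 5-fold
  cross-validated deviance, standardized features; selected = nonzero
  coefficients. With duplicated informative features the choice within
  the duplicate set is not unique.
* Features that are constant up to floating-point rounding (spread ≤
  1e−12 of their magnitude) are treated as constant: score 0, never
  selected. Without this, O(ε) spread produces spurious correlations.

Classifiers are scikit-learn defaults behind a per-fold standardizer:
LDA, KNN (k = 10, vote fraction as score, ties resolved toward the
negative class; k is clamped with a warning when a training fold is
smaller), SVM (RBF kernel, C = 1, signed decision value as score).
Standardization and every other fit statistic come from training folds
only; a test asserts the out-of-fold scores equal a manual
training-fold-only fit. The ROC is pooled over all out-of-fold scores
(stable at n ≈ 143 with k = 10, and equal to the normalized
Mann–Whitney U under midrank tie handling); accuracy uses each model's
default decision rule. A fold whose fit degenerates (e.g. LDA with one
class) is reported in `fold_errors` and falls back to the training
prior. The case-study grid is 7 analysis units × 3 models: the pooled
multi-organ unit concatenates the five non-whole-fish regions per
specimen with region-prefixed columns; when selection returns an empty
set the single top-|score| feature is used so every cell of the grid is
populated.

## The phantom generator

Specimens are rendered from geometric primitives: a circular-arc
midline of the stated body length and total curvature, a linearly
tapering body half-width, and discs for head, eye (inside the head),
pericardial sac and yolk, each with a distinct mean intensity, plus
additive Gaussian noise (SD 8 on the 8-bit scale). Each image also gets
a per-specimen illumination gain and offset (SD 12% and 6 gray levels
in cohorts), emulating the exposure variability of uncontrolled optical
photography; without it, class differences in organ sizes would leak
into first-order intensity summaries through an unrealistically
noise-free "composition" channel. The six masks satisfy eye ⊂ head ⊂
all_fish and heart, yolk ⊂ all_fish by construction (all_fish is the
union); `length` is realized as a one-pixel-wide midline band — the
closest mask realization of a body-length measurement. Rendering is
deterministic in the spec, and the full spec is stored in the study
metadata, so a cohort regenerates byte-identically.

Cohorts draw per-specimen anatomy from within-class normals
(curvature SD 4°, head SD 4 px, heart SD 2.5 px, body length SD 15 px,
eye SD 1 px, yolk SD 2 px around the defaults of a 512×384 image with a
300 px larva). The high-malformation class shifts curvature and heart
diameter up and head diameter down by the stated effect sizes in
within-class SD units; the default effect of 1.0 SD on each is a
moderate contrast chosen to sit in the same discrimination regime as
real early-malformation gradings (a single 1-SD parameter shift bounds
AUC near Φ(1/√2) ≈ 0.76). The default cohort size is 82 + 61. The
stability preset scales the larva to a third (all six masks below 2% of
the image area, the small-mask setting of a resolution analysis), with
6 specimens per cohort and a replicate cohort under a fresh seed. A
2560×1920 paper-scale image preset exists for on-demand high-resolution
runs; default sizes keep the full test suite at desk scale.

What passing on phantoms shows: the pipeline's bookkeeping,
determinism, statistical calibration (null cohorts select ~5% of
features at α = 0.05 and classify at chance) and its ability to recover
planted effects (5-SD whole-body effects give whole-fish AUC > 0.95
with a shape feature ranked first). What it does not show: anything
about real larval photographs — phantoms have none of the optical blur,
illumination gradients, debris, or anatomical idiosyncrasy of real
images, and the absolute M values of the stability analysis are
properties of the images analyzed, not of the method.

## Study management

Manifests are JSON, masks PNG, feature tables CSV (17 significant
digits, so export → import is the identity on doubles) or XLSX. Merging
an imported study requires the extraction settings fingerprint
(preprocessing mode, reduction factor when active, bin count,
discretization mode) to match exactly; registries union with local
order first. The problem sizes used by `scripts/acceptance.py` — six
small-mask specimens per stability cohort and the 82 + 61 case-study
design at 512×384 — are the package's default study conditions.
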