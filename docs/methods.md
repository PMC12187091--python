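# Methods

This note records the models, conventions and numerical choices behind
`radpath`, and what the synthetic generators do and do not emulate.

## Synthetic data: the study conditions

**Phantoms.** A phantom is a 3-D volume (default 24³ voxels at 1 mm
isotropic; the pipeline studies use 20³ for speed) with a centered spherical
ROI (default radius 8 voxels) filled with a Gaussian random field: white
noise smoothed by a Gaussian kernel whose width is the class's spatial
correlation length, then rescaled to the class mean and variance. The two
default classes share mean (100) and variance (400) and differ only in
correlation length (0.8 vs 2.0–2.2 voxels), so their first-order statistics
match and the planted contrast is a genuine co-occurrence (texture) signal —
this is why ANOVA selects GLCM-family features on phantom cohorts. Background
voxels are independent noise (mean 40, SD 5). Every generator is a pure
function of its spec, which includes the seed.

**Cohorts.** Covariates mimic the marginal structure of a head-and-neck
immunotherapy cohort: age ~ N(50, 11) clipped to [18, 80], 75 % male, N stage
in {0..3} with probabilities (0.1, 0.3, 0.4, 0.2), WBC ~ N(6.5, 1.8),
hemoglobin ~ N(135, 16), plus a site/batch label. Response is Bernoulli with
logit = logit(prevalence) + planted_effect · Σ scoreᵢ on standard-normal
planted score columns; the default prevalence 0.74 matches the responder
fraction such cohorts report. Survival times are exponential with hazard
λ₀ exp(β·risk) (λ₀ = 0.02 / month, default β = 0.8 on the normalized score
sum); censoring is uniform administrative, C ~ U(0, b), with b solved
numerically (Brent) so the expected censored fraction equals the requested
rate given the sampled hazards. These are marginal emulations only: no claim
of joint realism, covariate–outcome confounding, or site-specific case mix is
made, so passing tests demonstrate algorithmic correctness and planted-effect
recovery, not clinical performance.

**Nuclei scenes.** Cluster centers are uniform inside the canvas margin
(optionally rejection-sampled to a minimum separation for well-separated
scenarios); members are Gaussian offsets (default spread 25 px); each nucleus
is an ellipse with sampled axes (default major 12 ± 2, minor 8 ± 1.5 px) and
uniform orientation. Placement allows up to 10 % area overlap with earlier
nuclei — later placements win in the uint16 label mask — and repeated
placement failure raises an infeasible-density error. Rendering paints
near-white background (mean RGB > 210, exercising the tissue-mask rule),
stroma disks around clusters, hematoxylin-like nuclei, and DAB/gray-like
positive nuclei for IHC-like scenes, plus Gaussian color noise. Real H&E
texture, stain physics, and touching-nucleus segmentation ambiguity are not
modeled; the nucleus *segmentation* is an input contract (label masks), never
an algorithm of this package.

**Second reader.** `perturb_mask` offsets the signed Euclidean distance map
by a smooth random field clipped to ±magnitude voxels and re-thresholds, so
boundary displacement is bounded by the magnitude; magnitude 0 is exactly the
identity.

## Radiomics conventions

- Preprocessing follows min-max standardization to [0, 255], then cubic
  B-spline resampling to 1 mm isotropic (masks nearest-neighbor). Output grid
  size is `round(size · spacing / target)`; small mirror-boundary spline
  ringing near volume edges is expected and decays inward.
- Discretization is fixed bin *count* (default 25) over the ROI min–max with
  the top edge inclusive; a constant ROI collapses to level 1.
- Wavelet subbands use the decimated single-level orthonormal Haar transform
  with periodization boundary, chosen so Parseval energy conservation holds
  exactly (a testable invariant); subband letter *i* names the filter on axis
  *i* in (x, y, z) order. Subbands have halved grids, so the ROI mask is
  2× block-majority downsampled (block-any fallback if majority empties a
  non-empty mask). Volumes with odd dimensions are edge-padded (masks
  zero-padded) to even before the transform. Note the common radiomics
  default is an *undecimated* wavelet with a coif1 basis; results on the
  wavelet channels are therefore not numerically interchangeable with that
  convention.
- "Kernel sizes 1, 3, 5" for LoG are read as Gaussian scale σ in mm (the
  derived-image names `log-sigma-k-0-mm-3D` support this). The Gaussian
  kernel is truncated at 8σ so the discrete derivative weights sum to ≈ 0
  and constant volumes map to ≈ 0 response; responses are reported per mm².
- GLCM: symmetric matrices, Chebyshev distance 1, 13 unique 3-D directions,
  feature-then-average aggregation, log base 2, 0·log 0 = 0. Correlation of a
  degenerate (single-level) matrix is defined as 1, MCC of a single-level
  matrix as 1.
- GLDM: similarity tolerance α = 0 and *self-inclusive* dependence counting
  (an isolated voxel has dependence 1; the center of a constant 3×3×3 ROI
  has 27).
- First-order features use raw (non-discretized) ROI intensities; Entropy and
  Uniformity bin those intensities into the same fixed bin count. Kurtosis is
  the raw fourth standardized moment (3 for a normal); skewness and kurtosis
  of a constant ROI are reported as 0.
- Catalog arithmetic: 107 original = 14 shape + 93 non-shape; the 93
  non-shape features replicate over 8 wavelet subbands (744) and 3 LoG scales
  (279), giving 1,130 per sequence and 3,390 over T1/T2/T1C. Shape, GLSZM and
  NGTDM are enumerated in the catalog but not numerically extracted (returned
  as NaN markers); none of the selected model features needs them.

## Harmonization and selection

- ICC forms: ICC(3,1) (two-way mixed, consistency) for intra-reader and
  ICC(2,1) (two-way random, absolute agreement) for inter-reader, both from
  the mean-squares decomposition; retention requires both ≥ 0.75.
- Hausdorff distance is the classical max-min over surface voxels (not the
  95th percentile), in mm.
- ComBat: data are standardized per feature by the grand mean and pooled
  (population) variance; additive batch effects are removed exactly
  (γ̂ = batch means of the standardized data) and multiplicative effects are
  EB-shrunk toward a parametric inverse-gamma prior via the iterative
  moment-matched solve. Removing the additive effects without location
  shrinkage is a deliberate choice: it makes post-harmonization batch means
  equal (to float round-off) and preserves feature grand means, which are the
  package's tested invariants; the textbook full-EB location update is
  available as `location_shrinkage=True`. Consistency of the population
  variance convention makes a single batch an exact round-trip.
- Pruning is a greedy left-to-right pass in catalog order dropping any column
  with |r| > 0.99 against an already-kept column — deterministic, and the
  survivor is always the first in catalog order.

## Response modeling

- The seven classifier slots use scikit-learn estimators with small fixed
  hyperparameter grids (documented in `classifier_grid`); LightGBM fills the
  categorical-boosting slot. Comparison is stratified 5-fold CV AUC with a
  shared shuffled fold assignment per seed; the winner is refit on the full
  training set and its predicted probability is the Radscore.
- Stepwise logistic regression defaults to bidirectional BIC. The ln(n)
  penalty makes pure-noise candidate sets collapse to the intercept-only
  model in ≳ 90 % of simulations while a genuine OR = 3 predictor still
  enters; AIC (which admits a spurious term roughly half the time) and
  SPSS-style p-value entry/removal (0.05 / 0.10) are available options.
- Operating thresholds come from the Youden index on training data and are
  frozen for test data; Table-style sensitivity/specificity/accuracy are
  computed at that frozen threshold.
- DeLong's test uses placement values with sample covariance; CIs are Wald on
  the AUC scale clipped to [0, 1]; a zero-variance difference is flagged
  degenerate (p = 1 if the AUCs are equal, undefined otherwise).
- Hosmer–Lemeshow uses probability-decile groups (quantile bins, duplicate
  edges merged) with χ² = Σ (O − E)²/(E(1 − E/n)) on g − 2 df; the
  calibration curve's bias correction is 2·apparent − mean(bootstrap) over
  resampled decile curves at the apparent bin edges.
- The AUC sample-size search scans total N upward, forms the responder group
  as ⌊prevalence·N⌋ (floor; `group_rounding` exposes nearest/ceil), and
  requires Φ((θ₁ − θ₀ − z_{α/2}·SE₀)/SE₁) ≥ power with Hanley–McNeil
  variances at the null and alternative AUC. Floor rounding is the
  convention under which the search reproduces the published N = 37 at
  prevalence 0.70 (nearest rounding yields 38; its power at N = 37 is
  0.8996, just under 0.90).

## Survival modeling

- SMOTE interpolates a minority sample toward one of its k = 5 minority
  nearest neighbors with λ ~ U[0, 1]; original rows are passed through
  unchanged. In the survival study SMOTE is applied to (normalized features,
  survival time) jointly against the event label, so synthetic samples carry
  interpolated times — a documented approximation, as how resampling should
  treat censored times is genuinely underdetermined.
- Cox fits use lifelines (Efron ties); stepwise Cox is bidirectional by the
  partial-likelihood AIC. A small ridge penalizer (0.01) stabilizes
  near-separated study fits.
- Harrell's C counts a pair (i, j) comparable when the earlier subject i had
  an event (or tied times with j censored); risk ties score 0.5. The
  horizon-restricted C(t) simply drops pairs anchored on events at or after
  the horizon — no IPCW reweighting — and is therefore an approximation to
  time-dependent AUC-style estimators; reports label it as such.
- The optimal cutpoint maximizes the log-rank statistic over midpoints of
  consecutive distinct scores leaving ≥ 10 % of the cohort (minprop) on each
  side. The reported p is the naive log-rank p at the selected cut, not
  corrected for maximal selection.
- Cohort assembly for OS keeps subjects with an event or follow-up
  ≥ 24 months (configurable).

## Pathomics

- Tissue = mean RGB ≤ 210 (boundary pixel at exactly 210 counts as tissue);
  patches are non-overlapping 2,048 px tiles with partial edge tiles dropped
  by default and tiles below a 5 % tissue fraction skipped.
- Nuclear axes are the second-central-moment ellipse axes (scikit-image
  regionprops); the aspect ratio of a degenerate nucleus defaults to 1.
- The 150-vector uses per-slide min–max histogram edges (10 bins; a constant
  measurement puts all mass in bin 1), population moments, *excess* kurtosis,
  and Shannon entropy in bits of the normalized histogram (bounded by
  log₂ 10). Delaunay distances use slide-global centroids; degenerate sets
  (< 3 points or collinear) fall back to k-nearest neighbors with a warning.
- Birch auto-k: the CF tree is built at threshold t₀ = mean nearest-neighbor
  distance; subcluster centroids are merged by single-linkage cut at 5·t₀,
  and clusters smaller than max(3, 5 % of nuclei) are absorbed into the
  nearest major cluster (they are tail outliers split off by the fine
  threshold). Subclusters inside one density cluster sit 1–2·t₀ apart and
  chain together; genuinely separated clusters (≥ ~8·t₀) stay apart. This is
  one concrete reading of "automatically learning the number of clusters";
  an explicit `n_clusters` or CF `threshold` override is available. A
  largest-gap-ratio rule was evaluated and rejected as unstable (inter-cluster
  merge distances vary several-fold, masking the intra/inter gap).
- Cluster statistics: size = member count, dispersion = mean distance to the
  cluster centroid, extent = cluster diameter, Ball–Hall = mean over clusters
  of within-cluster-SS/size, Calinski–Harabasz = [SS_B/(k−1)]/[SS_W/(n−k)]
  (reported as 0, flagged, for k = 1).
- IHC unmixing works in optical density v = −log₁₀((I+1)/256); two stain
  vectors are completed with an orthogonal residual, the matrix inverted, and
  the positive mask thresholds the second stain channel (Otsu by default, a
  fixed threshold by config). Registration is translation-only phase
  cross-correlation with mean removal; full rigid rotation is out of scope.

## Correlation analysis

Spearman uses average ranks with the t-approximation p-value and
pairwise-complete missing handling (≥ 4 complete pairs per cell; constant
columns are NaN-marked). BH-FDR is applied over the pooled family of all
(radiomic × pathologic × marker) tests by default, per-marker as an option,
threshold 0.05. Strength bins treat 0.3 and 0.7 as moderate (inclusive).

## Study drivers and problem sizes

The end-to-end drivers run at desk scale by choice: the response study
defaults to 180 patients, 20³ phantoms, one sequence and original-image
features (the full 3,390-feature catalog over three sequences is available
through the same API and used in the extraction tests); the survival study
exercises the modeling stages on generated cohort feature tables, the
imaging path being covered by the response study; the correlation study
renders 60 scenes at 448². Every stage derives its randomness from the
config seed, and a fixed config reproduces bit-identical reports.

## Known limitations

- Wavelet-channel values are not comparable to undecimated-transform
  implementations (see above); shape/GLSZM/NGTDM are name-enumerated only.
- The horizon C-index ignores censoring weights (no IPCW).
- Generated cohorts have independent covariates; confounding structure and
  real class overlap are absent, so planted-effect AUCs are optimistic by
  construction.
- The bias-corrected calibration curve is a simple bootstrap shift, not the
  full resampling-validation procedure of dedicated regression-modeling
  packages.
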