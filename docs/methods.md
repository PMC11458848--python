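# Methods

`radrep` implements a perturbation-based repeatability analysis for CT
radiomic features and a repeatability-stratified prognostic modeling
pipeline for two survival endpoints (local recurrence-free survival, LRFS,
and overall survival, OS).  This note documents the models, the parameters
that matter, the synthetic data the package ships with, and the design
choices made where the design was genuinely open.

## 1. The repeatability model

A radiomic feature is *repeatable* when re-measuring the same tumor yields
the same value.  Test–retest imaging is rarely available for esophageal
cancer under definitive chemoradiotherapy, so re-measurement is simulated by
perturbing each image/mask pair:

1. **Rigid rotation** of image and mask about the craniocaudal axis through
   the mask centroid (trilinear for the image, nearest-neighbour for the
   mask), emulating variation in patient posture.  Default angles are drawn
   uniformly from ±10°; a guard rejects |angle| > 30° as no longer a
   plausible positioning perturbation.
2. **Contour randomization**: SLIC supervoxels (default expected volume
   64 mm³) are built over the dilated mask region, and each supervoxel is
   included in the redrawn contour independently with probability equal to
   its overlap fraction with the original mask.  This makes the *expected*
   redrawn volume equal the original volume.  The result is restricted to
   its largest 26-connected component so texture matrices see a contiguous
   region.  Supervoxels fully inside (outside) the mask are always (never)
   included, so a mask that is exactly a union of supervoxels is a fixed
   point.

One perturbation realization = rotation followed by contour randomization of
the rotated mask (the combined chain; a rotation-only or contour-only chain
is available through `PerturbationSpec`).  The default is 10 realizations
per case; the reduced-scale study configuration uses 3 (see §6).

Repeatability is scored with the one-way, random-effects,
absolute-agreement ICC across the k = p + 1 exchangeable repeats
(original + p perturbed):

    ICC = (MSB − MSW) / (MSB + (k − 1)·MSW)

with MSB/MSW the between/within-subject mean squares of a one-way ANOVA.
The one-way model is the right one here because perturbation realizations
have no rater identity.  Raw ICC can be negative (down to −1/(k−1)); the
reported value is clamped to [0, 1].  A feature with no variance at all
(identical across every patient and repeat) is perfectly repeatable by
convention (ICC = 1).  Features are split into equally sized high- and
low-repeatable groups at the *median* ICC of the volume-independent feature
set; ties at the cutoff are resolved by sorting on (ICC, feature id) and
splitting at the midpoint, which guarantees group sizes differ by at most
one.

## 2. The feature engine

Features follow the IBSI-style definitions used across the radiomics
literature: 18 first-order intensity statistics, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM and 5 NGTDM features — 93 per image and bin width.
The image branch enumerates 14 filtered images (original, 5
Laplacian-of-Gaussian scales, 8 one-level wavelet sub-bands) and 5 fixed
bin widths {8, 16, 32, 64, 128}, for 93 × 14 × 5 = 6510 values per ROI.

Conventions that required a decision:

* **Preprocessing order.** Volumes are resampled to 1 × 1 × 1 mm
  (trilinear image / nearest-neighbour mask).  The mediastinal display
  window (default level 40 HU, width 400 HU) is applied *only* to the
  original-image branch: LoG and wavelet responses are signed band-pass
  signals that HU clamping would destroy.
* **Discretization.** Fixed bin width anchored at the ROI minimum:
  `level(x) = floor((x − min)/w) + 1`; invariant to adding a constant to
  all ROI values.  First-order features are recomputed at every bin width
  even though only Entropy and Uniformity depend on it, so that the
  93 × 14 × 5 accounting holds.
* **Matrix conventions.** Distance-1 neighbourhoods, 13 unique 3-D
  directions for GLCM/GLRLM with per-direction features averaged (not
  merged matrices); 26-connectivity for GLSZM zones, GLDM dependence
  (α = 0) and NGTDM neighbourhoods.  Matrices are restricted to the gray
  levels present in the ROI.  Directions with no voxel pair (degenerate,
  sliver-thin ROIs) are dropped from the GLCM average.
* **Degenerate inputs.** Single-gray-level ROI: Contrast 0, Correlation 1,
  Imc1/Imc2 0, MCC 1, NGTDM Contrast/Busyness/Complexity 0; NGTDM
  coarseness is capped at 1e6 when its denominator vanishes; a constant ROI
  has Skewness = Kurtosis = 0.  These conventions keep every feature vector
  complete, which the ICC stage requires.
* **Filter defaults.** LoG σ ∈ {1, 2, 3, 4, 5} mm, scale-normalized (σ²∇²G);
  wavelet family `coif1` with symmetric padding, each sub-band reconstructed
  back to the original grid by zeroing the other seven before the inverse
  transform (so the eight reconstructions sum to the original image).
* **Mesh volume** (the confounder for the volume-dependency filter) is the
  divergence-theorem volume of the marching-cubes isosurface at 0.5 on the
  zero-padded binary mask.

Every texture family is verified against an independently written
brute-force oracle (explicit voxel loops and scalar formula evaluation) on
randomized small grids, plus hand-enumerated toys.

## 3. Feature selection and models

The cascade (training set only, per endpoint, per repeatability group) is
strictly nested:

1. **Volume dependency**: remove features with Pearson r² ≥ 0.6 against
   tumor mesh volume (zero-variance features have r² defined as 0).  This
   runs before the median-ICC grouping.
2. **Redundancy**: single-linkage clusters of |Spearman ρ| ≥ 0.8
   (connected components of the thresholded correlation graph); one
   representative per cluster, chosen as the member with the smallest
   univariate Cox Wald p (ties break on the feature id, making the output
   order-independent).  The published description of this step is not
   detailed enough to pin the statistic; this concretization is our
   interpretation and both thresholds are configurable.
3. **Survival relevancy**: univariate Cox per standardized feature, keep
   Wald p < 0.05, uncorrected — a per-feature screen, consistent with the
   large surviving counts reported in this literature (a family-wise
   correction would leave almost nothing).
4. **LASSO-Cox**: coordinate-descent L1 path (scikit-survival's Coxnet,
   l1_ratio = 1) with the penalty chosen by K-fold cross-validated
   partial-likelihood deviance (glmnet-style held-out deviance
   −2·[ll_full(β) − ll_train(β)]).  The deviance-minimum rule is the
   default; the 1-SE rule is available (at 60 training patients it proved
   too aggressive, usually selecting nothing, which is why it is not the
   default here).  10 folds by default, 5 in the reduced-scale
   configuration.
5. **Events-per-variable guard**: the final multivariate model keeps at
   most `n_events / 10` covariates (largest |penalized coefficient| first;
   `SelectionConfig.epv`, disable with `None`).  The usual small-sample
   safeguard for Cox models — without it the group whose LASSO admits more
   features (typically the low-repeatable one) shows inflated in-sample
   optimism that has nothing to do with repeatability.

Features are standardized with training-set mean/SD before screening and
penalized fitting (penalization requires a common scale); the scaler is
frozen into the fitted results and applied unchanged to validation data.

The modeling surface is statsmodels-like: `RadiomicsCoxModel(features,
times, events).fit()` returns a results object carrying the selection
trace, the multivariate Cox fit (lifelines, Newton–Raphson on the
Efron-corrected partial likelihood), coefficient table via `summary()`,
and the *signature* = linear predictor Σβx.  The training-set median of
the signature is the risk cutoff, applied unchanged to validation
patients.  `ClinicalCoxModel` screens clinical factors by univariate Cox
(p < 0.05) before a multivariate fit; `FusionCoxModel` adds the radiomic
signature to the screened factors as one covariate (a degenerate constant
signature is dropped, so the fusion then reduces exactly to the clinical
model).

The univariate screens use an in-package vectorized single-covariate Cox
(Newton iterations, Breslow tie handling — identical to Efron on the
tie-free continuous survival times used throughout); fitting thousands of
features through a general-purpose fitter would dominate the pipeline's
runtime.  It is cross-checked against lifelines in the tests.

## 4. Evaluation

* **Harrell's C-index** with a seeded patient-bootstrap percentile CI;
  model comparison by paired patient bootstrap of the C difference, with a
  two-sided p from the bootstrap z (a t-test-on-replicates variant is
  retained because parts of this literature quote a Student t-test for this
  comparison; the bootstrap default is the statistically cleaner choice).
* **Time-dependent AUC** at 12/24/36/60 months: IPCW estimator with
  cumulative cases / dynamic controls and Kaplan–Meier censoring weights
  1/G(T⁻) on cases.  Without censoring it reduces exactly to the rank AUC
  of the event indicator.  The incident-case variant was not chosen because
  the clinical question ("who has failed by t years?") is cumulative.
  Marker comparison at a horizon uses the classic DeLong test on the
  subjects whose status at the horizon is known.
* **Risk stratification**: high/low by the training-median cutoff; the
  group hazard ratio comes from a single-covariate Cox fit; Kaplan–Meier
  curves and the log-rank test quantify separation.
* **Baseline cohort comparison**: per-variable r × 2 chi-square between
  training and validation cohorts, with the Yates continuity correction for
  2 × 2 tables (this choice uniquely reproduces the published two-decimal
  p-values 0.77/0.15/0.06 for the gender, tumor-length and T-stage tables).

## 5. The synthetic cohort

No CECT cohort is shipped, so `radrep.synthetic` generates one that
preserves the *mechanisms* the analysis depends on:

* **Phantom CT** (48³ voxels at 1 mm by default): lung (−700 HU) laterally,
  mediastinum (40 HU) centrally; an ellipsoidal tumor (default semi-axes
  12/10/9 mm) with +60 HU mean offset, a Gaussian random field
  (correlation length 3 mm, sd 35 HU), focal low-attenuation inclusions
  (−250 HU over ~8% of voxels, correlation length 2 mm — the air lumen and
  necrosis that give real esophageal tumors their wide intensity range and
  sharp internal edges), and white noise (sd 12 HU).  The inclusions matter:
  without them, band-pass sub-bands have so little dynamic range that
  coarse-bin discretization collapses to a single gray level and the
  bin-width repeatability trend degenerates.
* **Latent traits** are exact by construction: standard-normal deviates
  `z_volume` (scales tumor radii by `exp(0.25 z)`) and `z_texture` (scales
  texture sd by `exp(0.4 z)`).  The true log-hazard is a known linear
  function of these deviates and the clinical indicators, enabling
  parameter-recovery and oracle-dominance tests.
* **Clinical covariates** are drawn from the training-cohort margins of the
  source population (age, sex, performance status, location, tumor length,
  T, N, dose, concurrent chemotherapy).
* **Survival**: Weibull proportional hazards, shape 1.2, scale ≈ 42 (LRFS)
  / 49 (OS) months (≈50% three-year survival at η = 0); endpoint-specific
  log hazard ratios on z_volume, z_texture, age, length, T4 and
  chemotherapy; LRFS and OS are independent given the covariates (their
  dependence is not modeled).  Censoring is uniform(0, 150 months)
  truncated at an administrative 84 months — conventional, since the source
  cohorts' censoring distributions are not published.
* **The cross-institution shift**: validation-site phantoms draw
  *per-patient* acquisition parameters — intensity scale uniform in
  (1.0, 1.3) and noise sd uniform in (12, 30) HU.  Heterogeneity is the
  point: a site-wide constant shift would preserve patient rankings and
  leave rank-based metrics (C-index) almost untouched, whereas real
  cross-institution variation (tube current, habitus, contrast timing,
  reconstruction) differs scan by scan and selectively scrambles
  noise-sensitive — i.e. low-repeatability — features.

What the generator does **not** emulate: anatomically realistic esophagus
and organ geometry, scanner-specific noise texture and reconstruction
kernels, inter-observer segmentation styles, correlated competing risks,
and cohort-specific effect sizes.  Passing tests on this cohort therefore
demonstrate that the *pipeline* is correct and that the repeatability
mechanism behaves qualitatively as in the source study — not that any
particular clinical C-index would be attained on real data.

## 6. Problem sizes and numerical choices

The package's study configuration (`reduced_scale_config`) runs the whole
two-site analysis at desk scale: 60 + 30 patients, 32³ phantoms, the
original + 8 wavelet sub-band filter bank, bin widths {8, 128}, 3
perturbation realizations, 5 CV folds.  These sizes keep a full run in the
minutes range while preserving every qualitative contrast (bin-width and
family repeatability trends, high-vs-low cross-site behaviour).  The
feature engine itself always supports the full 6510-feature configuration,
which the accounting checks exercise.

Numerical details: Cox convergence tolerance 1e-7 on coefficients
(lifelines `precision`); Newton screens iterate to 1e-9 with steps clipped
to ±2 and coefficients to ±50 (a screen that diverges — separation — is
reported as p = NaN and dropped with a warning); the Coxnet path uses 50
penalties with `alpha_min_ratio` 0.01, and fold-specific path truncations
are skipped rather than extrapolated; bootstrap CIs use 1000 resamples by
default (200 inside the pipeline loop); all randomness flows from explicit
integer seeds through counter-based `SeedSequence` spawning, so every run
is bit-reproducible and enlarging a cohort never reshuffles existing
patients.

## 7. Known limitations

* The perturbation parameters of the source study (angles, supervoxel size,
  realization count) are not public; defaults follow the cited perturbation
  literature and are configuration-exposed, so absolute ICC values are not
  comparable — only the relative structure (trends across filters, bin
  widths, families) is meaningful.
* The redundancy step and the exact window/interpolator of the source
  study are interpretations (documented above).
* GLCM Idmn/Idn normalize by the count of gray levels present in the ROI;
  implementations that normalize by the theoretical maximum level will
  differ on sparse ROIs.
* The two-group experiment is stochastic at reduced scale: individual seeds
  can show an inverted cross-site contrast; the documented behaviour is the
  median over seeds.
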