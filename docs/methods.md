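# Methods

`fltrad` implements an early-response analysis for paired FLT-PET scans of
breast lesions under neoadjuvant chemotherapy: radiomic features are
extracted from the baseline scan (FLT1) and the scan after the first
chemotherapy cycle (FLT2), screened for robustness against contour
variability, converted to percentage changes, and used in L1-penalized
logistic models of the PET (EORTC) and pathological (residual cancer burden)
response. Because no patient images are publicly deposited, the package
ships a synthetic-cohort generator that reproduces the study conditions with
known ground truth; every downstream stage is validated against it.

## Image model and SUV conversion

Volumes are 3D scalar fields with (x, y, z) voxel spacing in mm; the
standardized uptake value is

    SUV = activity [kBq/ml] x body weight [kg] / injected dose [MBq],

dimensionless under the 1 g/ml soft-tissue convention. Activity is assumed
decay-corrected by the scanner; no lean-body-mass correction is applied
(body weight is the stated convention). Masks are binary, stored as 0/1
unsigned bytes in NIfTI/NRRD.

## Geometry

* **Resampling.** Feature extraction resamples each lesion (cropped to its
  bounding box plus an 8 mm margin) to 1 mm isotropic voxels: trilinear for
  the volume, linear + 0.5 threshold for the mask. The output grid is
  *edge-aligned* with the input (voxel edges coincide), which preserves the
  physical extent and avoids systematic threshold ties when one spacing is
  an integer multiple of the other; out-of-extent samples use
  nearest-neighbor extrapolation so constant fields stay constant.
* **Contour perturbation.** The four contour variants (original, +1 mm,
  +2 mm, -1 mm) are generated *after* resampling, so ±1 mm is exactly one
  voxel. Expansion/contraction is distance-transform based and
  spacing-aware: expansion adds background voxels within delta mm of the
  contour; contraction removes foreground voxels within delta mm of the
  background. 3D-isotropic perturbation is used (in-plane-only is the
  alternative reading; the 3D choice is symmetric on the isotropic grid). A
  contraction that empties a mask yields a flagged degenerate variant that
  cohort loops drop and log. On a unit grid the 1 mm shell adds only
  face-adjacent voxels (diagonals sit at sqrt(2) mm), so dilated volumes run
  ~5% below the continuum (r+1)^3/r^3 ratio — a discretization property, not
  an error.
* **Mirroring.** The contralateral background VOI is the lesion mask
  reflected across the volume's geometric mid-sagittal plane. Real data with
  an asymmetric field of view can supply an explicit midline axis.

## Features

The implemented vector has 46 indices; 42 of them form the published
contour-robust reference set (the remainder are the first-order Mean, Max,
Skewness and Kurtosis from the same family).

* **SUV statistics** — max, mean, and peak; SUV_peak is the mean over a
  ~1 cm^3 sphere (radius 6.2 mm, all voxels whose centers lie within it,
  clipped at the volume boundary) centered on the voxel maximizing that
  sphere mean. The local intensity peak uses the same sphere centered at the
  global in-mask maximum. For response coding these are computed on the
  native grid (as vendor consoles do); for the radiomic table they are
  computed on the resampled grid.
* **Intensity (ID_*) statistics** are computed on raw, undiscretized SUV
  values (binning is fixed only for texture and IVH): population moments,
  CoV = sd/mean, quartile coefficient of dispersion, robust MAD restricted
  to [P10, P90], median absolute deviation as the mean deviation about the
  median, energy, RMS.
* **IVH** uses fractional intensities gamma = (x - min)/(max - min): V90 is
  the volume fraction with gamma >= 0.90, I10 the smallest gamma attained by
  the top decile of voxels, and the AUC the mean of the volume-fraction
  curve over a 1000-point gamma grid. A constant VOI defines gamma = 1
  (V90 = AUC = 1) to avoid NaN propagation.
* **Discretization** is fixed-bin-number with 32 levels:
  level = 1 + floor(32 (x - min)/(max - min)), max mapped to 32, constant
  VOIs to level 1.
* **Texture matrices** use one merged-direction convention throughout:
  GLCM symmetric over the 13 unique 3D directions at Chebyshev distance 1;
  GLRLM merged over the same 13 directions with run percentage normalized by
  voxels x directions; GLSZM zones are 26-connected equal-level components;
  GLDZM distances are per-zone minimum Chebyshev distances to the VOI border
  (edge voxels at distance 1, the image border counting as outside); NGLDM
  uses the 26-neighborhood with dependence threshold alpha = 0 and
  dependence size j = k + 1; NGTDM coarseness carries a 1e-6 guard so a flat
  VOI maps to 1e6. Degenerate-input rules (IMC1 = 0 for zero marginal
  entropy, single-voxel VOIs dropped as degenerate variants) keep the ICC
  and LASSO stages free of NaNs. Every family is pinned exactly against
  brute-force voxel-scanning oracles in the test suite.

## Robustness screening

Percentage changes (FLT1 - FLT2)/FLT1 x 100 are computed per contour
variant, and each feature's subjects x 4-variants matrix is scored with the
single-measurement absolute-agreement ICC(A,1) from the two-way
random-effects ANOVA,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with the F-based 95% CI (McGraw & Wong form, cross-checked against pingouin
to numerical precision). A feature is retained when the CI lower bound is
>= 0.60, inclusive. Negative estimates are reported as computed; zero-variance
features are flagged undefined and excluded. Subjects with a missing
(degenerate) variant are dropped per feature and logged. The same screen can
be applied to per-timepoint absolute values.

## Response coding

Lesion SUV statistics are background-corrected by subtracting the matched
statistic of the mirrored contralateral VOI, floored at 0. EORTC classes
from corrected SUV_max: CMR when FLT2 uptake has vanished into background
(corrected value <= a configurable tolerance, 0 by default; the pipeline
uses 0.1 SUV, about two standard deviations of breast background noise, so
noise in the mirrored VOI cannot flip a call); PMD above a +25% increase;
PMR at a >= 15% reduction (the one-cycle bound; configurable); SMD
otherwise. Complete response is coded 1 throughout (CMR and pCR); residual
cancer burden categories map RCB-0/I -> pCR, RCB-II/III -> pPR, and the RCB
category itself is accepted as input (computing the continuous index from
histopathology is out of scope). Concordance is the diagonal of the PET x
pathology cross-table with a two-sided Fisher exact p (hypergeometric
enumeration semantics, validated against a full-enumeration oracle for all
small tables).

## Response models

`LassoLoocvClassifier` follows the glmnet workflow: covariates standardized
(mean 0, sd 1; reported coefficients stay on that scale), intercept
unpenalized, a 100-point descending log-spaced penalty grid from lambda_max
= max|X'(y - ybar)|/n (the smallest penalty with all slopes zero) down to
lambda_max/100. lambda_min minimizes the leave-one-out binomial deviance
(the stable criterion at n = 15; the misclassification rate at the 0.5
cutoff is reported separately, ties predicting class 1). The final model is
refit on all data at lambda_min. Fold standardization reuses the full-data
scale; per-fold solutions warm-start along the grid. The underlying
penalized fits use the saga solver (tol 1e-6, seeded, coefficients below
1e-10 truncated to exact zeros so the lambda_max boundary is crisp).
Elastic-net and ridge variants are deliberately not exposed.

## Synthetic cohorts

The generator emulates the acquisition and outcome structure of the study:

* Two scanner geometries — A: 3.9 x 3.9 x 4.25 mm voxels, B: 4.1 x 4.1 x
  3.0 mm — with 10/15 of patients on A; dosing at 3.5 MBq/kg capped at
  350 MBq; weights ~ N(70, 10) kg.
* Ellipsoidal lesions with randomized 6-11 mm semi-axes (lesion size is not
  reported per patient; this range matches primary breast lesions at PET
  resolution), placed in one lateral half; the contralateral VOI is the
  mirrored mask.
* Heterogeneous uptake: a Gaussian random field (white noise smoothed at a
  5 mm correlation length), exponentiated for positivity, min-max scaled so
  the hottest voxel hits the drawn baseline SUV_max (3-10) and the coldest
  in-mask voxel stays above background. Noise is additive Gaussian on
  background (sd 0.05 around SUV 0.5) and multiplicative lognormal (sd
  0.05) on lesion voxels, reflecting intensity-dependent PET count noise.
* Outcomes: 9/15 responders. 7/9 of responders show complete disappearance
  of uptake (decline drawn from 0.95-1.00, dropping the lesion below
  background), the rest decline partially (0.40-0.70); non-responders
  decline 0-0.10. RCB categories follow the observed frequencies
  (responders: RCB-0 with probability 0.9 else RCB-I; non-responders:
  RCB-II with probability 0.85 else RCB-III).
* One master seed; per-patient streams are spawned from it, so cohorts are
  reproducible under partial regeneration.

What the generator does **not** emulate: scanner point-spread/time-of-flight
physics, attenuation and scatter, respiratory motion, irregular lesion
topology, nodal disease, and inter-observer contouring. Passing tests
therefore demonstrate the correctness and stability of the *analysis*, not
clinical performance on real scans.

## Validation designs

Two planted-signal designs (module `fltrad.experiments`) exercise the
screening and modeling stages on 30-patient cohorts with partial declines
only (0.40-0.70 vs 0.00-0.10), where lesions stay textured at both
timepoints:

* **Robustness trial.** Contour-*sensitive* decoy features (values redrawn
  independently per contour variant) are appended to the percentage-change
  table; the filter must retain the contour-stable SUV statistics and
  reject the decoys.
* **Model recovery.** Under the generator's uniform multiplicative decline,
  the percentage change of *every* raw-intensity statistic is collinear with
  SUV_max's, and L1 selection within a collinear group is arbitrary. The
  planted-signal covariate set therefore pairs percent-change SUV_max with
  the scale-invariant indices (intensity ratios, IVH, all discretized
  texture families — fixed-bin-number levels are unchanged by uniform
  rescaling), which carry no label information by construction. The model
  must select SUV_max with a positive sign (complete response = 1) and reach
  a low LOOCV error.

Problem sizes used throughout validation: 30-patient cohorts with 5-9 mm
lesions for the planted-signal trials (10 seeds), 6-patient cohorts for the
end-to-end determinism check, and 15-patient default cohorts for the
headline pipeline run — each chosen as the smallest size at which the
corresponding claim is statistically meaningful.

## Known limitations

* Texture aggregation is fixed to the merged-direction convention;
  per-direction averaging is not offered.
* Morphological/shape features are not implemented (none survive contour
  perturbation screening by design of that family).
* The EORTC call uses background-corrected SUV_max; the uncorrected variant
  is available through the same functions but is not the pipeline default.
* Tables of model coefficients from n = 15 cohorts are descriptive: with
  leave-one-out tuning at that size, coefficient values are unstable even
  though selection behavior is reproducible.
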