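# Methods

This note documents the models, conventions and numerical choices behind
`renoct`, in the spirit of a statistical-software methods appendix. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Single-kidney GFR (mL/min/1.73 m²) and split renal function (SRF, %) are
normally measured with dynamic renal SPECT. The package estimates both
from non-contrast CT given per-kidney segmentations of renal parenchyma
(label 1) and hydronephrosis (label 2). Kidneys are analyzed individually
(two rows per patient); SRF is constrained to sum to 100 % per patient.

## Preprocessing

Order is fixed: **resample → clip → z-score**.

* Resampling: trilinear for the image, nearest-label for masks
  (`scipy.ndimage.zoom`, `grid_mode=True` so cell centers — not edge
  points — are aligned and physical extent is preserved; the label set can
  never grow). The conventional target grid is 256 × 256 × 80; the phantom
  study extracts at the phantom's native grid (below).
* Intensity window: width 260 HU, level 60 HU → clip to [−70, 190] HU.
* z-score over the whole clipped volume. A constant volume maps to zeros
  with a warning. All radiomic intensity features are therefore computed
  on dimensionless z-scored values; this is a documented choice (the
  alternative — raw HU — changes feature scales but not the pipeline).

## Radiomic features

Implemented in-repo with definitions that an independent brute-force
program can verify (the test suite contains such oracles for every
formula):

* **Shape (14)** — mesh volume/surface (marching cubes at the 0.5 level
  on the padded binary mask, physical spacing), sphericity
  (36π V²)^⅓ / A, voxel volume, surface-to-volume ratio, maximum 3D and
  in-plane diameters (convex-hull pairwise distances), PCA axis lengths
  (4·√eigenvalue of the voxel-center covariance), elongation, flatness.
  Shape is computed once, on the unfiltered geometry.
* **First-order (18)** — energy, total energy (voxel volume × energy),
  histogram entropy/uniformity (fixed-bin-width discretization), min/max,
  percentiles, mean/median, IQR/range, (robust) mean absolute deviation,
  RMS, population skewness/kurtosis (kurtosis not excess-corrected; both
  0 for constant regions), variance.
* **GLSZM (16)** — zones are 26-connected components of equal discretized
  gray level; P(i,j) counts zones of level i and size j; the standard 16
  emphasis/non-uniformity/variance/entropy functionals. Σ P(i,j) = N_z is
  asserted on every extraction.
* **NGTDM (5)** — per in-region voxel, the mean gray level of its
  26-neighborhood restricted to the region (center excluded); voxels with
  no in-region neighbor are dropped. Busyness, coarseness (capped at 1e6
  for perfectly uniform regions), contrast, complexity, strength; all
  defined 0 when only one gray level is present.

**Discretization** uses a fixed bin width (level = ⌊(x − min)/w⌋ + 1).
The default `bin_width = 0.25` is expressed in z-score units, giving
roughly 25–30 occupied levels over a typical parenchymal region — the
fixed-bin-width convention applied to standardized intensities.

**Filters.** Intensity families are recomputed on derived volumes:
sign-preserving square (sign(x)·x²/max|x|), sign-preserving logarithm
(sign(x)·log(1+|x|), rescaled to the input range), spacing-aware gradient
magnitude, and the 8 sub-bands of a single-level 3D `coif1` discrete
wavelet decomposition, each reconstructed back to the original grid so the
same masks apply (LLL…HHH naming). With all families and filters enabled a
kidney yields 965 feature columns (14 shape + 18 + 16 + 5 intensity
features × 12 filter variants × 2 regions) plus a `hydronephrosis_present`
indicator; kidneys without hydronephrosis get zero-filled hydronephrosis
intensity features so tables stay rectangular. The historical figure of
2260 features depends on a specific extractor configuration and is not a
target.

## Feature selection

1. **Repeatability** — ICC(2,1) (two-way random effects, absolute
   agreement, single measurement) between the manual-mask and
   auto-mask extractions of every feature; features with ICC < 0.9 are
   excluded (boundary value retained). Absolute agreement is deliberately
   chosen over consistency: a constant offset between the two extractions
   is a real reproducibility defect. For [1,2,3,4] vs [2,3,4,5] the
   closed form gives 10/13 ≈ 0.769, pinning the choice. Zero-variance
   features score 1 if identical, else 0, and are logged.
2. **Redundancy** — pairwise |Spearman ρ| on the ICC-retained features;
   pairs with |ρ| > 0.9 (strictly) are processed in descending |ρ|; in
   each pair still intact, the member with the larger mean |ρ| against
   all other original features is dropped (static means, single pass; name
   ties drop the lexicographically later feature). The procedure is
   deterministic and column-order invariant, and the final set never
   contains a pair above the threshold (asserted at run time). |ρ| is
   used because a strong negative correlation is equally redundant.

## Estimators

* **rGFR** — elastic net on the retained features, standardized
  internally, coefficients reported on the original scale. Mixing ratio
  grid {0.1, …, 1.0}; penalty grid of 60 values log-spaced over six
  decades below the lasso-null penalty; selection by ten-fold
  cross-validation **grouped by patient** so paired kidneys never straddle
  a fold. A zero-variance target degrades to an intercept-only model with
  a warning.
* **rcGFR** — ordinary least squares of reference GFR on
  {rGFR, age, sex, BMI} with backward elimination at p ≥ 0.05 (intercept
  always kept; singular designs raise an error naming the collinear
  columns; zero-variance candidates are dropped up front with a note).
* **rcSRF** — each kidney's percentage of the patient's total estimated
  GFR. Estimates are floored at 0.01 mL/min/1.73 m² before the ratio so a
  negative linear-model output cannot leave [0, 100]; pairs sum to exactly
  100.
* **pSRF / hSRF** — simple linear regression of SRF on the kidney's
  fraction of total parenchymal (resp. hydronephrosis) volume,
  predictions clipped to [0, 100]. A patient with no hydronephrosis has an
  undefined hydronephrosis share; both kidneys then receive the
  uninformative prior 0.5. If the whole training cohort lacks
  hydronephrosis, hSRF is reported as a constant 50 % and flagged.
* **rcphSRF** — backward MLR combining {rcSRF, pSRF, hSRF}.

Training fits use the manual-segmentation feature table; the auto-style
table drives the ICC filter and the Dice evaluation. This keeps the
reference standard in the fit while still rejecting features that are
fragile under automatic segmentation.

## Evaluation statistics

* Lin's CCC with population (n-denominator) moments —
  2·cov/(var x + var y + (x̄ − ȳ)²); CI via Fisher z with Lin's asymptotic
  variance. CCC ≤ |r| always (attenuation).
* Reduced major axis: slope = sign(r)·sd(y)/sd(x) through the means
  (reference on the x axis).
* Bland–Altman: mean difference ± 1.96 × sample SD.
* Wilcoxon signed-rank for paired error comparison: exact distribution
  for n ≤ 25 without ties, normal approximation with tie correction
  otherwise; zeros dropped; all-zero differences give p = 1.
* AUC by the Mann–Whitney pair-counting estimator with half-credit ties;
  variance/CI and the paired AUC-difference test by DeLong structural
  components (placement values). Scores are oriented so the poor-health
  class is positive.
* Exact binomial (Clopper–Pearson) 95 % CIs from Beta quantiles for
  accuracy/sensitivity/specificity; this reproduces published intervals
  such as 0/4 → (0, 60.2) % and 2/2 → (15.8, 100) %.
* Baseline cohort comparison: two-sided Mann–Whitney U (continuous),
  Pearson χ² without continuity correction (categorical) — the latter
  reproduces the published p = 0.853 for a 74/54 vs 69/48 sex table.
* Health-status cutoffs, poor-health class positive, boundary handling as
  published: GFR ≤ 30 impaired; GFR < 10 non-functioning; SRF < 15
  nephrectomy; SRF < 45 lower function; SRF ≤ 60 non-dominant.
* Rates are kept at full precision internally and rounded only when
  rendered.

## Phantom cohort

The simulator emulates the clinical cohort the estimators target, not
kidney anatomy:

* Grid 128 × 96 × 40 at 1.5 × 1.5 × 5 mm (5-mm slices; extent
  192 × 144 × 200 mm). Both kidneys are rendered in one volume's
  left/right halves; masks are per-side.
* Each kidney is an ellipsoid (base semi-axes 27 × 29 × 54.5 mm, 10 %
  lognormal per-axis variation, jittered center). With probability 0.25 a
  kidney is atrophic (axes × U(0.72, 0.90)). With probability 0.5 it is
  hydronephrotic: a water-density core whose target volume is lognormal
  (median 70 mL, σ = 1.2, capped at the kidney volume) dilates the outer
  envelope by 80 % of the core volume — so hydronephrosis mostly expands
  the kidney rather than consuming parenchyma, and cohort RHV is
  zero-inflated with a heavy tail (SD > mean).
* Intensities: background −45 HU, parenchyma ≈ 35 ± 5 HU with a
  Gaussian-random-field texture (amplitude ≈ 12 HU, correlation length
  6 mm), water-like core ≈ 5 HU, white noise 5 HU.
* Clinical covariates: age ~ N(52.8, 13.7²) truncated to [18, 90], 57.8 %
  male, BMI ~ N(23.9, 3.3²).
* Reference GFR is **linear in quantities the imaging pipeline can
  measure**: GFR = 0.20·RPV + 0.60·(parenchymal HU) + 0.30·(texture
  amplitude) − 0.05·RHV − 0.25·age + N(0, 7.5), floored at 0; SRF follows
  from the two kidney GFRs (50/50 if both are 0). This makes end-to-end
  parameter recovery a meaningful validation target standing in for an
  unavailable SPECT reference. Defaults were calibrated once so a default
  200-patient cohort reproduces the clinical moments (mean RPV ≈ 153 mL,
  RHV ≈ 35 mL zero-inflated, GFR ≈ 40 ± 13).
* The "automatic" segmentation is emulated by shifting the signed
  boundary distance with a smooth random field plus small-component
  dropout; severity 0 is the identity, larger severity monotonically
  lowers Dice, and the default 0.6 was calibrated once to a mean
  parenchymal Dice ≈ 0.86 (within the 0.80–0.95 band typical of automatic
  renal segmentation).

**What passing tests do and do not show.** The phantom has ellipsoidal
geometry, stationary texture, no respiratory/partial-volume artifacts, no
perirenal structures, and a GFR that is exactly linear in five measurable
quantities. Recovery results therefore validate the machinery (features,
selection, fitting, evaluation, determinism), not clinical accuracy on
real CT.

## Problem sizes and seeds

All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns (per-patient substreams), so cohorts
are reproducible regardless of iteration order and pipeline outputs are
byte-identical across reruns. The simulation study and the acceptance
script use 100-patient cohorts (200 kidneys) with a 60/40 patient-level
train/test split; the moment checks use 200 patients. Patient-level
splitting prevents leakage between paired kidneys.

## Known limitations

* No DICOM ingestion and no automatic segmentation model: masks are
  inputs; NIfTI only.
* Texture families beyond GLSZM/NGTDM (GLCM, GLRLM, GLDM) are not
  implemented; the feature catalog is configurable but not exhaustive.
* The CCC confidence interval uses the large-sample Fisher-z form; for
  n < 10 it is unreliable (reported as NaN below n = 4).
* hSRF is only informative in cohorts with hydronephrosis variance; the
  uninformative-prior convention (0.5 share) otherwise makes it constant.
* The wavelet basis (`coif1`, single level, symmetric padding) is fixed;
  other bases change filtering-feature values.
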