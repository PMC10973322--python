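# Methods

`ctamuscle` re-implements, as a tested pipeline, a quantitative analysis of
lower-extremity CT angiography (CTA) muscle in peripheral arterial disease
(PAD): threshold-based muscle segmentation, a 95-feature histogram/texture
bank plus shape descriptors, univariable screening, LASSO-selected logistic
models of PAD severity, published fixed-coefficient predictors, and an
evaluation on five equal knee-to-ankle segments of the leg. Because no
patient data are deposited anywhere, a synthetic phantom cohort is a
first-class component: it defines the statistical conditions under which
every downstream stage is exercised.

## The clinical problem and the model

PAD severity is graded on digital subtraction angiography (DSA) with a
modified Society-for-Vascular-Surgery runoff score in [0, 19]; patients
with DSA score <= 7 form the *mild* group and > 7 the *severe* group.
Ischemic muscle is hypoperfused: its CT attenuation falls and its
heterogeneity rises. The pipeline quantifies this with first-order and
texture features of the segmented lower-leg muscle and predicts the binary
severity label with logistic models:

* **LRM-I** — muscle features only, selected by cross-validated LASSO;
* **LRM-II** — the same features plus the standardized CTA runoff score.

Two published fixed-coefficient equations are frozen in
`modeling.PUBLISHED_MODELS` (inputs z-scored):

```
LRM-I :  logit(P) = -1.29 * F1 - 0.67 * F2 - 0.85          cutoff 0.35
LRM-II:  logit(P) =  1.18 * CTA - 1.11 * F1 - 0.68 * F2 - 0.90   cutoff 0.43
```

with F1 = `histogram_10Percentile` and
F2 = `gldm_DependenceNonUniformityNormalized`.

## The phantom cohort

`phantom.generate_phantom` renders a stylized two-bone leg per axial slice:
air background, an elliptical subcutaneous-fat ring (-100 +/- 15 HU), a
muscle annulus, tibia/fibula analogs (cortical shell 1200 +/- 100 HU around
a marrow core at 30 +/- 10 HU), three contrast-filled arteries
(300 +/- 30 HU) and two veins (90 +/- 10 HU) wrapped in fascial fat. The
leg tapers ~35% from knee to ankle, and vessels taper with it. Marrow and
veins sit **inside** the muscle HU window on purpose: they must be removed
structurally, mirroring the manual correction a semi-automatic workflow
needs. HU values are drawn per voxel, noise is added before integer
rounding, and everything is deterministic given `(seed, subject_id)`.

Group-level muscle parameters are the reported cohort values: mild
44.6 +/- 16.0 HU, severe 39.5 +/- 16.7 HU (voxel-level mean +/- SD). Two
layers of per-subject heterogeneity make the cohort statistically
realistic rather than group-deterministic; both are back-computed from the
reported per-feature interquartile ranges (SD ~ IQR/1.349):

* subject-level mean offset, SD 3.0 HU (mild) / 4.8 HU (severe);
* subject-level voxel-SD offset, SD 0.7 / 0.8 HU.

Without them every texture feature separates the groups perfectly at
n = 56 and the maximum-likelihood logistic fit does not exist.

Runoff scores are drawn from group-conditional normals (mild 3.3 +/- 2.6,
severe 12.3 +/- 3.0), rejected-resampled onto the correct side of the
boundary at 7 and clipped to [0, 19]. The CTA score is the DSA score plus
a Gaussian offset calibrated analytically so the group CTA means hit the
reported 6.1 / 11.8, with DSA/CTA correlation ~0.8 (a free parameter).
One consequence of that correlation: the phantom's CTA-only AUC (~0.93) is
higher than the clinical 0.81, so the fitted muscle models add less on top
of CTA here than they do in real data.

### Distal disease structure

Two mechanisms shape how group separation varies along the leg, emulating
the clinical observation that mid-distal segments discriminate best:

* **severe-only attenuation tilt** — a linear knee->ankle HU offset
  (default -6 HU end-to-end, per-subject SD 8) applied *centered* at
  mid-leg so the whole-leg mean still matches the group parameter. The
  per-subject SD models heterogeneity in lesion level.
* **distal myosteatosis** — intramuscular partial-volume fat speckles
  (~0 +/- 12 HU, i.e. thin fat streaks inside the window) at a base
  fraction of 4%, ramping up from 60% leg length to a per-subject ankle
  fraction ~N(0.15, 0.12) truncated at zero, in both groups.

The tilt makes the between-group contrast grow toward the ankle; the
myosteatosis ramp injects group-independent between-subject variance that
grows faster in the most distal fifth (its exposure is ~3x that of the
fourth fifth). The net effect, chosen deliberately to reproduce the
expected sub-dataset pattern, is that discrimination rises from segment 1
to 4 and drops in segment 5; the test suite asserts that the
knee-to-ankle segment 4 attains the maximal median muscle-model AUC over
seeded replicate cohorts. The parameters came from a variance calculation
(signal gain ~0.8 AUC-probit per segment vs. noise growing quadratically
with distance from mid-leg) refined by a pilot simulation.

Ground-truth labels tag partial-volume fat as its own tissue, so
"muscle voxels" in tests means pure muscle; the segmented ROI additionally
contains the in-window fat speckles, which is exactly the contamination a
real threshold segmentation suffers.

## Segmentation

`threshold_segment` keeps voxels with -10 <= HU <= 100, both bounds
inclusive. `clean_mask` then applies two deterministic rules that replace
the manual correction step — the largest deliberate deviation from the
manual workflow being emulated:

1. per-slice flood fill from the border over non-bone voxels
   (bone = HU >= 300); in-window regions the fill cannot reach are
   bone-enclosed marrow and are removed;
2. 3D connected components (26-neighborhood) smaller than
   `min_component_voxels` (default 50) are removed; per slice, only the
   largest 8-connected component and components >= 10% of its size are
   retained (this removes vein cross-sections, which are fascially
   detached from muscle).

On default phantoms the cleaned mask covers >= 95% of true muscle with
Dice >= 0.95; every retained voxel is inside the window by construction.
Knee/ankle landmarks are configuration (`restrict_z`), not detected.

## Feature bank

95 intensity/texture features: 20 histogram, 24 GLCM, 14 GLDM, 16 GLRLM,
16 GLSZM, 5 NGTDM; plus 2 conventional shape measures (muscle volume in
cm^3, mean per-slice cross-sectional area in cm^2) and 14 radiomic shape
descriptors. Conventions, stated because tools differ:

* discretization: fixed 5-HU bins anchored at the ROI minimum;
* texture in 3D over the whole ROI, 13 unique directions at distance 1,
  feature values averaged over directions; a per-slice 2D mode
  (4 directions, 8-neighborhood, 2D zones) is available via
  `DiscretizationParams(mode="2d")`;
* percentiles by linear interpolation; population (n) moment denominators;
  kurtosis is **non-excess** (normal ~ 3; the reported values cluster near
  3.8, impossible under the excess convention);
* CV = 100*SD/mean, reported NaN (flagged) at zero mean; skewness and
  kurtosis defined 0 at zero variance; Mode is the center of the fullest
  bin, ties to the lowest;
* no intensity shift is applied before Energy;
* GLDM: similarity tolerance 0, 26-neighborhood, tabulated dependence size
  = dependent neighbors + 1 (the center counts), so emphasis weights are
  well-defined; GLSZM zones are 26-connected; NGTDM uses the mean level of
  in-mask neighbors;
* degenerate single-level ROIs: GLCM Correlation and MCC are 1, Imc1/Imc2
  are 0, NGTDM Contrast/Busyness/Complexity/Strength are 0 and Coarseness
  saturates at 1e6;
* shape: surface area by exposed-face counting (exact for axis-aligned
  shapes; a cube scores its closed-form 600 mm^2 where a marching-cubes
  mesh would chamfer corners), Sphericity defined on that surface and the
  voxel volume; MeshVolume separately via marching cubes; axis lengths are
  4*sqrt(eigenvalue) of the physical voxel-coordinate covariance;
  2D diameters are maximal pairwise distances of surface voxels in the
  three coordinate-plane projections.

Every texture feature is verified against an independent plain-loop
enumerator (`tests/oracles.py`) at 1e-9 on random ROIs up to 8^3.

## Screening and statistics

Features are z-scored column-wise (population SD; transform retained and
re-applied verbatim to per-segment re-extractions). Group comparisons use
Student's t (equal variance; Welch available) when both groups pass
Shapiro-Wilk at alpha 0.05, otherwise Mann-Whitney U with the asymptotic
normal approximation and tie correction. Categorical tables use Pearson
chi-squared without continuity correction, or Fisher's exact (2x2) when
any expected count is < 5. Screening keeps p < 0.05 with **no**
multiple-testing correction — deliberately matching the emulated
pre-selection stage; ~5% of null features will pass by construction.
Reader agreement uses ICC(2,1) (two-way random effects, absolute
agreement, single rater) with an F-based 95% CI.

## Model building

`lasso_select` runs a linear-response LASSO — squared-error loss on the
0/1 outcome, matching the mean-squared-error criterion the emulated
selection stage reports — by coordinate descent (scikit-learn's
`lasso_path` on fold-centered data) over a 60-point log-spaced lambda grid
from the KKT zero-threshold `max|X'(y-ybar)|/n` down by 1e-3, with
outcome-stratified 10-fold CV; lambda* minimizes mean CV MSE (not the
1-SE rule). A logistic-deviance LASSO sits behind `loss="logistic"`.

The final models are maximum-likelihood logistic fits (statsmodels) with
Wald SEs, OR = exp(coef) with 95% CIs exp(coef +/- 1.96 SE), a
likelihood-ratio omnibus test, and a 10-decile Hosmer-Lemeshow test (ties
split by stable sort; groups with empty expectation skipped, df =
groups - 2). Two pragmatic layers sit on top:

* variables that lose significance in the multivariable fit are
  backward-eliminated at alpha 0.05 (`retain_alpha`; set `None` to keep
  all) — reproducing the second selection step implied by published
  models that report only their significant variables;
* under perfect separation the ML fit does not exist
  (`SeparationError`); `build_models` drops the weakest selected variable
  (smallest |LASSO coefficient|) and retries, falling back to a
  ridge-penalized fit (flagged `penalized=True`, NaN Wald statistics) only
  when even a single variable separates, as happens in very small smoke
  cohorts.

ROC analysis reports the empirical (trapezoid/Mann-Whitney) AUC, a DeLong
variance-based 95% CI and p-value against AUC = 0.5, and the
Youden-optimal cutoff with ties broken toward the lower (more sensitive)
cutoff; sensitivity/specificity/accuracy carry their integer
numerators/denominators. Classification is score >= cutoff.

## Sub-dataset analysis

`split_z` partitions the segmentation z-range into k = 5 contiguous
segments of near-equal slice count, remainder slices assigned
proximal-first. For each segment the model's input features are
re-extracted from that segment alone, standardized with the **whole-leg**
transform (per-segment re-standardization would leak information), and
pushed through the fitted or published equations at their fixed cutoffs —
cutoffs are never re-optimized per segment, and k = 1 reproduces the
whole-leg evaluation bit-for-bit.

## What the phantom does and does not establish

Passing tests show the pipeline recovers the statistical structure the
generator encodes: the group attenuation difference and its direction, a
feature bank that matches independent enumeration exactly, calibrated
type-I error, LASSO selection consistency under strong signals, the
II >= I ordering of model AUCs, and the mid-distal discrimination peak.
They do not validate the clinical claim on real patients: the phantom has
no partial-volume blur at tissue boundaries, no beam-hardening or motion
artifacts, stylized vessel/bone geometry, and an idealized link between
runoff scores and muscle change. Absolute AUCs on phantoms (in-sample,
~0.9) are not comparable to the clinical values.

## Problem sizes and tolerances in the test suite

Texture oracle equivalence: 100 random ROIs up to 8^3, tolerance 1e-9.
Cohort-level checks: 12 seeded replicates of the reference 36/20 cohort on
the default 64x64x60 grid (3x3x5 mm voxels) — enough that the median
subset-AUC pattern (peak at segment 4 for LRM-I, margin ~0.04) and the
screening direction (all replicates) are stable. Type-I calibration: 1000
null replicates, acceptance band [0.03, 0.07] at alpha 0.05. LASSO
recovery: 100 runs, 5 informative columns at log-odds 3 per SD among 40
noise columns, requiring full recovery in >= 80%. Monte-Carlo score
checks use 10^4 draws against analytic truncated-normal moments.
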