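# Methods

## The flow-void measurement chain

The choriocapillaris is imaged as an en-face OCTA slab; regions whose
decorrelation signal falls below the device's detection floor appear dark
and are read as *flow voids* (absent or very slow flow).  `ccflow`
implements the widely used adaptive-threshold quantification:

1. **Superficial binarization.** The superficial retinal plexus slab is
   thresholded to a binary vessel mask.  The thresholding rule is Otsu's
   between-class-variance maximizer by default; a `mean + k·SD` rule is
   available.  Otsu was chosen because it is parameter-free and suited to
   the bimodal vessel/background histogram; a constant (contrast-free)
   image yields an empty mask plus an explicit warning rather than an
   error.
2. **Projection-artifact exclusion.** Superficial vessels cast spurious
   flow signal onto deeper slabs.  The vessel mask — optionally dilated by
   `round(dilation_um / um_per_px)` pixels of 8-neighbourhood dilation,
   default 0 µm — defines the *artifact mask*; those pixels are excluded
   from every subsequent statistic, both numerator and denominator.
3. **Speckle smoothing.** Gaussian filter with σ specified physically
   (default 20 µm; ≈ 1.013 px at a 6 mm / 304 px scan), reflect padding at
   the border.  σ = 0 disables smoothing.
4. **Adaptive threshold.** `I_mean − η·SD` with η = 1 by default (the
   multiplier with the best published repeatability for this protocol).
   Mean and SD are computed over the analyzable (non-artifact) pixels with
   the population (N) denominator; both choices are configurable
   (`stats_support="full"`, `sd_mode="sample"`) because the original
   MATLAB implementations do not state them.  Pixels *strictly below* the
   threshold are voids; ties are background ("fell below" read literally).
5. **Morphometry.** Connected components of the artifact-excluded void
   mask under 8-connectivity (the particle-counting default in ImageJ-style
   tools; 4-connectivity available).  No minimum-size filter is applied and
   edge-touching components are kept.  A void split in two by an artifact
   counts as two components; the result notes record this convention.
   Reported metrics: `area_pct = 100 · void px / analyzable px`,
   `mean_size_px = void px / count`, and `count`.

Numerical notes: images are processed at native bit depth as real-valued
intensities with no normalization (the threshold is shift/scale covariant);
the integer identity `count · mean_size_px = total void pixels` is exact by
construction since the mean is stored as the integer total divided by the
count.  Degenerate inputs (fewer than 2 analyzable pixels, zero analyzable
area) raise typed errors.

**Scan QC.** Quality control consumes human-assigned boolean flags
(poor clarity, local weak signal, motion artifact, segmentation failure,
eye disease, missing); automatic quality scoring is out of scope.  A record
with any flag is excluded once, attributed to the first matching reason in
a fixed order (eye disease first, then missing/poor-quality imaging),
so multi-flagged records never double-count and the attrition identity
`enrolled − Σ exclusions = analyzed` holds exactly.

## Synthetic scenes

The generator emulates only the features the measurement chain is
sensitive to, not the device physics:

- **Vessels** are random-walk branching strokes (disk-stamped, 1–2 px
  radius, angular jitter, occasional branching) grown until the mask covers
  the requested density (default 0.25).  Only the shadow-mask geometry
  matters downstream, so no physiological tree model is attempted.
- **Voids** are ellipses (aspect ratio U(1, 2), uniform orientation,
  overlaps unioned) whose areas follow a truncated power law — many small
  voids, progressively fewer large ones, the size structure reported for
  real choriocapillaris flow deficits.  The truncated Pareto keeps an
  analytic mean and CDF for testing.  Defaults: exponent 2.0 on
  [4, 1500] px.
- **Speckle** is multiplicative gamma noise with unit mean, parameterized
  by its coefficient of variation (default 0.60) — the standard first-order
  OCT speckle approximation.
- **Projection artifact**: intensities under the vessel mask are raised by
  a configurable fraction (default 0.25).
- Images are quantized to 16-bit counts (background 20 000) so fixture
  round-trips are bit-exact.  One `SeedSequence` per scene is split into
  per-stage sub-streams, so each stage's output is independent of the other
  stages' draw counts.

Defaults were calibrated once so that the default measurement chain reports
metrics in the range typical of treated-hypertension cohorts (area
≈ 16–18 %, mean size ≈ 10–11 px, count ≈ 1000); no published noise or
contrast statistics exist for the source scans, so this calibration targets
the output metrics, not the device.  `void_fraction_target` switches the
generator from a Poisson void count to implanting voids until a stated area
fraction is reached (the last void is clipped to the remaining deficit),
which ground-truth-recovery studies need.

What passing tests on these scenes do **not** show: robustness to motion
artifacts, vignetting/defocus, segmentation errors, or physically realistic
coherence speckle — real scans fail in ways the simulator does not emulate,
which is exactly why scan-level QC flags exist.

## Synthetic cohorts

Each simulated participant carries independently drawn covariates (age
56 ± 11 y, 45 % women, 16 % diabetes, daytime systolic BP 131 ± 13 mmHg
with a nocturnal dip, log-normal creatinine and urine MCR, …) and
contributes two eyes with probability 0.93 (≈ 1.9 eyes/subject).  Eye-level
outcomes follow a linear model with per-10-unit effects for age and BP, a
subject-level random intercept shared by both eyes, and eye-level noise.
The default variance components fix the implied inter-eye correlation
σ_b²/(σ_b² + σ_e²) at 0.65 for area and size and 0.49 for count, matching
the values reported for this measurement; default embedded effects are the
headline associations (−0.13 area per 10 mmHg daytime SBP, +0.21 size and
−21.21 count per 10 years of age, +13.89 count per 10 mmHg nighttime DBP).
Covariates are mutually independent by construction, so univariate slopes
are unconfounded — real cohorts are not so kind, which is why the
multivariate machinery exists.

The "overall" ambulatory BP summary is the plain mean of all readings;
with the day window sampled every 20 min and the night window every 30 min
this weights day readings 3:1, and the simulator reproduces that weighting
as 0.75·day + 0.25·night.

## Derived covariates

- **ABPM windows**: day = [06:00, 22:00) local time (half-open: a reading
  stamped 22:00 is a night reading), unweighted arithmetic means per
  window; an empty window gives NaN with a warning, not an error.
- **BP-control strata** (intensive/standard/poor) partition the positive
  axis at 120 and 140 mmHg systolic, classified on the overall 24-h mean
  (configurable to the daytime mean).
- **eGFR**: 2009 CKD-EPI creatinine equation in its sex-stratified
  published form (female base 144, male 141; κ = 0.7/0.9; α = −0.329/−0.411;
  0.993^age), creatinine converted from µmol/L at 88.4; the race
  coefficient is off by default and available as a flag.  The function is
  continuous at the κ knot and strictly decreasing in creatinine.
- **Urine MCR** is stored in mg/mmol with an explicit mg/g conversion
  (× 8.84 via the creatinine molar mass).

## Statistics

GEE with Gaussian family, identity link, exchangeable working correlation
on subject clusters and robust (sandwich) standard errors; CIs are
normal-approximation Wald intervals on the robust SEs, p-values from the
normal reference.  Clusters of size 1 have no intra-cluster pairs, so the
estimator is switched to the independence structure and reproduces OLS
point estimates exactly — a property the tests pin to 1e-8.  Reference
levels: male sex, never-smoker, intensive BP control, one medication
class.  Complete-case analysis per model.  Covariate selection: forced
{age, sex, diabetes} plus any factor with univariate p strictly below 0.10
(categorical factors screened on their smallest level p); the six
ambulatory-BP summaries are near-collinear and each enters its own
multivariate model.

Descriptive comparisons route each continuous variable by a Shapiro–Wilk
test on pooled within-group residuals at α = 0.05: normal → one-way ANOVA
(mean ± SD), otherwise Kruskal–Wallis (median (IQR)).  Categorical
variables use chi-square, switching to Fisher's exact test when any
expected cell is below 5; for tables larger than 2×2 (where no exact
r×c test is available in SciPy) the Fisher p-value is computed by
fixed-margin Monte-Carlo sampling with an add-one correction, internally
seeded for determinism.  One-level factors are reported as not applicable
with p = 1.

## Pipeline

`ccflow run` executes simulate → quantify → analyze → report under a single
declarative config (YAML-loadable) and a single seed; intermediates are
plain TIFF/PNG/CSV/JSON so any stage can be inspected or re-run alone, and
`manifest.json` records the config echo, per-stage counts (with the
attrition identity asserted) and SHA-256 digests of every output.  The
manifest deliberately carries no wall-clock timestamps so identical configs
produce byte-identical manifests.  Stage failures abort with the stage name
and exit status 1; configuration errors exit 2.

## Problem sizes used in the checks

The validation suite uses full-protocol 304-px scenes where the physical
scale matters (ground-truth recovery, default metrics), 128–152-px scenes
for the conservation and monotonicity sweeps (the identities are
scale-free), 200 replicate cohorts of 85 subjects (≈ 164 eyes) for the
effect-recovery and coverage study, cohorts of 500 subjects for the
inter-eye correlation targets (averaged over five replicates, since a
single draw's Monte-Carlo SD is the same order as the ±0.05 band), and
1000 null replicates for the type-I-error check.

## Known limitations

- The threshold support, SD estimator and area denominator are stated
  nowhere in the source protocols; the defaults here (analyzable-pixel
  support, population SD, analyzable-pixel denominator) are one reasonable
  reading and all are configurable.
- "Void size" is the per-eye mean component area; if a distribution-mode
  statistic from the particle-size histogram was intended instead, values
  will differ.
- The synthetic cohort cannot stand in for the clinical cohort: observed
  coefficient values from real data are not reproducible from this package,
  only the machinery that would estimate them.
- Gaussian smoothing is applied to the whole image before artifact
  exclusion, so intensity within ~4σ of an artifact border leaks across it;
  voids must clear the artifact mask by the kernel support to be fully
  independent of it.
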