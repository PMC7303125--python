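# Methods

## Scope and data model

All imaging operations act on a `VoxelVolume` (a 3-D scalar grid with mm
spacing, origin and modality) and a `VOIMask` (an aligned integer label
image with named regions). The package assumes **co-registered** inputs: CT,
PET and masks share one voxel grid. No resampling or registration is
performed — grid mismatch beyond 1e-6 mm per axis is an error
(`validate_alignment`), and every operation that pairs a volume with a mask
validates alignment first. NIfTI-1 is the only supported container (CT as
int16 HU, PET as float32; region names in a JSON sidecar). CT values are
integer HU throughout; non-integer input is rounded half away from zero, so
rounding is symmetric about water (0 HU).

## Marrow compartment classification

A marrow voxel with attenuation `h` is classified by the threshold scheme
`(yellow_low, bmat_rm, rm_bone)`, default `(−200, 115, 300)` HU:

* BMAT: `yellow_low ≤ h < bmat_rm`
* red marrow: `bmat_rm ≤ h ≤ rm_bone`
* bone: `h > rm_bone`
* out of range: `h < yellow_low`

The quoted clinical intervals overlap at their endpoints ("−200 to 115" and
"115–300"); making the partition half-open at 115 and closed at 300 renders
it exhaustive and keeps "above 300" strictly bone. Out-of-range voxels
(likely air or artefact) remain in the Ad.V/Ma.V denominator by default,
because adiposity is defined relative to *total* marrow cavity volume; a
flag restricts the denominator to in-range voxels.

Ad.V/Ma.V = 100 × (BMAT voxels) / (total VOI voxels). It is invariant under
voxel-spacing rescaling; absolute volumes scale with the spacing product.

## ROC cutpoint derivation

The fat/red-marrow cutpoint is derived from per-voxel HU of a fat-rich VOI
(positives) versus a fat-deficient VOI (negatives). Because fat is the
low-attenuation class, the rule is **positive iff HU < t**. Over an integer
threshold grid (default: pooled min to pooled max + 1, so the curve spans
(0,0)–(1,1)):

* sensitivity(t) = P(HU_pos < t), specificity(t) = P(HU_neg ≥ t), both as
  exact count ratios;
* AUC is the trapezoid area over (1 − specificity, sensitivity), which on
  this grid equals the Mann–Whitney estimate P(pos < neg) + ½ P(tie)
  exactly;
* the cutpoint maximizes Youden's J = sens + spec − 1, ties broken toward
  the **lowest** threshold (favors specificity for the fat class). A
  closest-to-(0,1) criterion is available. The optimality criterion used by
  the original clinical derivation is not recorded; Youden is the standard
  reading of "greatest sensitivity and specificity" and is stated in every
  output manifest.

For equal-variance Gaussian classes the population Youden optimum is the
midpoint of the means — the property used both in tests and in the phantom
defaults. The −200 HU lower bound is treated as a fixed scheme parameter,
not ROC-derived.

## SUV, decay correction, %ID/g

SUV is body-weight normalized: `SUV = C / (D/BW)` with C in kBq/mL, D the
injected dose (MBq, converted to kBq) and BW the body mass (g). A uniform
concentration equal to D/BW yields SUV 1 everywhere (mass balance). PET
volumes are assumed scanner-decay-corrected to injection time; per-class
SUVs are means over the segmented voxels, and empty classes are absent from
the result rather than zero.

Gamma counts are converted as `MBq = cpm × counter factor`, back-corrected
to injection time by `A0 = A · 2^(Δt/T½)` with T½ = 109.77 min (physical
¹⁸F half-life), and reported as `%ID/g = 100 · A0 / D / m`. The correction
is one-directional: negative elapsed times are rejected.

## Rod-phantom calibration

Calibration regresses rod-**mean** HU on known rod density by ordinary
least squares (one point per rod, mirroring per-rod VOI extraction; an
option weights rods by voxel count). The two-parameter fit is solved in
closed form from the normal equations. `density_at` inverts the line and
flags extrapolation outside the calibrated density span. The bone/marrow
density cutoff used to split small-animal bones has **no default**: the
original cutoff is unrecorded, and guessing one silently would invite
misuse, so it is a required, logged configuration parameter. The human
threshold scheme is never applied in mouse mode.

## Capacity model

Per subject, with body mass M (kg) and height H (m):

* marrow mass = 0.05 · M, split 70/30 between fat and haematopoietic
  tissue; `V_BMAT = 0.05·M·0.70/0.92`, `V_RM = 0.05·M·0.30/1.06` (L).
  The split is applied to marrow **mass** by default although the 70/30
  figures are usually quoted for volume: the mass reading reproduces both
  reported cohort-mean volumes (2.27 L and 0.84 L) from a single body mass
  (59.67 kg), whereas a volume split fixes their ratio at 7/3 ≈ 2.33,
  inconsistent with 2.27/0.84 ≈ 2.70. The literal volume split is provided
  as `split_mode="volume"`.
* bone volume = bone_mass(H) / 1.245; muscle volume =
  pct(sex, age)/100 · M / 1.055.

The height→bone-mass coefficients and the muscle-percentage table are
reference-population inputs, not package constants. The shipped defaults
are clearly labelled synthetic placeholders with plausible adult
magnitudes; outside simulation mode the pipeline refuses to use them
without explicit acknowledgment in the config.

Capacity index = volume × mean SUV per tissue (arbitrary units, L·SUV);
`percent_of_muscle` normalizes by the skeletal-muscle index and is
invariant to any common rescaling of the SUVs. Volumes are reported to
2 decimal places (litres).

## Synthetic data: what it emulates and what it does not

The generators produce every pipeline input from one integer seed via named
`SeedSequence` substreams (one per compartment/purpose), so outputs are
bit-identical per (config, seed) and independent of generation order.

* **CT/PET phantom.** Each compartment's HU is Gaussian; marrow regions mix
  BMAT and RM voxels with an *exact* split (`floor(fraction·n)` fat voxels,
  positions shuffled), so ground-truth fractions are realized proportions
  and recovery tests are sharp. Default HU distributions are constructions
  — scWAT N(−100,20), BMAT N(42,30), RM N(188,30), trabecular bone
  N(412,55), cortical bone N(1000,100), muscle N(55,10) — chosen so the
  equal-variance midpoints sit at the diagnostic cutpoints (115, 300 HU).
  Region geometry is consecutive voxel runs: every downstream statistic is
  mask-based, so shape carries no information. The phantom has no skeleton
  anatomy, no partial-volume blur, no beam hardening and no scanner noise
  model; passing recovery tests therefore demonstrates correctness of the
  estimators under the stated voxel model, not robustness to scanner
  physics.
* **Rod phantom.** Rod voxels are Gaussian around `slope·ρ + intercept`
  (defaults 1000 and −800: soft tissue near water ≈ 280 HU at 1.08 g/mL,
  densest rod 770 HU), noise SD 10 HU, 500 voxels/rod.
* **Cohort.** Ages, heights and masses are Gaussian (non-positive draws
  resampled); defaults follow the room-temperature clinical cohort (n=10,
  age 51.5±19.6 y, 20% male). Height/mass summaries are not reported for
  that cohort, so defaults (1.66±0.09 m, 59.7±8.0 kg) were chosen to match
  its BMI (≈ 20.7 kg/m²) and to place the mean mass at the value consistent
  with the reported mean tissue volumes.
* **Adipocyte annotations.** Cell areas are lognormal around 2×10⁻³ mm²
  (≈ 50 µm cells); unilocular cells carry 0–2 small droplets, multilocular
  3–8.

## Numerical choices

* Thresholds, HU and histogram bins are integers; histograms are 1-HU bins
  over a configurable range (default −500…1500) with out-of-range values
  tallied separately so voxel counts are conserved.
* Cohort histogram summaries average per-subject *proportions* (each
  subject normalized by its own VOI size) and report SEM with ddof = 1;
  at least two subjects are required.
* Specificity is computed as an exact count ratio rather than 1 − FPR to
  keep agreement with exhaustive enumeration bit-exact.
* OLS uses closed-form normal equations (2 parameters; numerically benign
  at these scales); r² is clamped to [0,1].
* Marrow classes are coded uint8 arrays internally (object arrays of enums
  break numpy elementwise equality).
* Degenerate inputs fail loudly: empty regions, empty samples, single-rod
  calibrations, zero masses/doses, negative elapsed times and misaligned
  grids all raise typed errors.

## Problem sizes

Tests and the acceptance script use 100,000 voxels per ROC class or marrow
VOI, 5 rods × 500 voxels for calibration, and cohorts of 10–10,000
subjects — sizes at which the standard errors of every recovered quantity
(≈ 0.1 HU for compartment means, ≈ 0.15 percentage points for adiposity,
≈ 0.5% for the calibration slope) sit well inside the assertion tolerances.

## Known limitations

* No partial-volume correction, kinetic modelling, SUL/lean-mass SUV
  variants, or attenuation-correction handling.
* The capacity model propagates no uncertainty beyond cohort SD; bone and
  muscle models are only as good as the supplied reference coefficients.
* The ROC module is strictly two-class and unsmoothed, with no confidence
  intervals on the AUC.
* DICOM, registration and resampling are out of scope by design.
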