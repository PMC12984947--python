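# Methods

## Measurement model

The quantity of interest is the fat-to-muscle proportion of the
supraspinatus, FTMP (%) = 100 · V_fat / V_muscle, computed from a 3D MRI
volume and a manually delineated anatomical ROI. The model is purely
intensity-based: within the ROI every voxel is assigned to muscle, fat
or neither by fixed signal-intensity windows, and compartment volumes
are voxel counts times the voxel volume. No morphological cleanup,
surface meshing or interpolation enters the reported numbers — the exact
additivity V_muscle + V_fat = V_total and V_total + V_unclassified =
V_ROI is the signature of pure voxel counting, and the test suite
enforces it on every input.

Assumptions: the two tissues are separable by a scalar intensity
threshold at the acquisition protocol in use; the ROI is given (drawn by
an operator) and correct; voxels are small relative to tissue structures
except at boundaries, where partial-volume averaging is expected and is
deliberately surfaced as the unclassified ("gray zone") compartment
rather than forced into either class.

## Threshold calibration

Candidate cutoffs are the midpoints between consecutive distinct sorted
probe values, plus one sentinel below the minimum and one above the
maximum (the degenerate all-fat and all-muscle classifications standing
in for the ROC curve's ends). Fat is the positive class — it is the
brighter tissue on T1 — so sensitivity is fat recall (value ≥ cutoff)
and specificity muscle recall. The returned cutoff maximises Youden's
J; when several candidates tie, the lower median of the tied candidates
is returned, a deterministic choice that is always itself a candidate.
For fully separated classes the optimum is unique and equals the
midpoint of the gap between max(muscle) and min(fat); the whole gap is
reported alongside, since every cutoff inside it is equivalent. The
small-sample exact distribution of J is not computed; calibration
reports the operating point, not an inferential p-value.

The working segmentation windows — muscle [1000, 3500], fat ≥ 3600 —
are the calibrated bracket rounded outward so that an explicit
(3500, 3600) gray zone remains. Calibration itself never rounds;
rounding is a downstream policy. Intensity thresholds are
protocol-specific (field strength, sequence, vendor scaling) and must be
recalibrated for any other scanner; nothing in the package transfers
them.

Interval conventions: the muscle window is closed on both ends, fat is
closed below ("3600 or higher"). ROI values below the muscle window are
unclassified, not muscle.

## Phantom model

Phantoms exist to close the loop between generator truth and pipeline
output; they emulate the measured data's first-order structure, not MR
physics.

* **Geometry.** The ROI is an ellipsoid (default 2:1:1 aspect, long axis
  in-plane) at the acquisition's voxel spacing (0.234 × 0.168 × 2.0 mm).
  Cohort phantoms size the ellipsoid so the ROI holds the target muscle
  volume plus fat.
* **Composition.** The fat voxel count is the integer nearest to
  N·t/(100+t) for target FTMP t, placed either as isolated voxels
  ("dispersed", interstitial fat) or as unions of small random spheres
  ("clustered", streaky infiltration). Both are plausibility constructs;
  no spatial statistics of real infiltrate are claimed.
* **Intensities.** Pure voxels draw uniformly from the observed
  per-tissue ranges (muscle 1002–3448, fat 3600–9652); a
  clipped-normal model is available behind `intensity_model="normal"`.
  The ranges are ranges of *measured* signal, so the generator treats
  them as hard bounds: additive Gaussian noise (`noise_sd`, signal
  units, default 0) jitters each voxel *within its class range* and is
  clipped at the range ends. Noise therefore perturbs values, never
  class membership — a phantom whose noise relabelled voxels would
  violate the ranges it is defined to emulate.
* **Partial volume.** With `partial_volume_width` w > 0, every voxel
  within w voxels (city-block) of a muscle–fat interface mixes one
  muscle and one fat endmember linearly by a subvoxel occupancy drawn
  uniformly, bounded so the mixed signal stays strictly below the
  pure-fat floor. The bound encodes an identifiability fact: a mixed
  voxel bright enough to classify as fat is observationally identical to
  a fat voxel, so the generator's "mixed" ledger tracks exactly the
  voxels that can leave their class. Consequently enabling mixing can
  only move fat out of the fat window and boundary voxels into the gray
  zone: measured FTMP never rises above the sharp-boundary value, which
  is the testable form of the partial-volume underestimation mechanism.
* **Cohorts.** Per-group FTMP ~ Normal(1.8, 0.8), (2.8, 0.7),
  (0.5, 0.4) % and muscle volume ~ Normal(8520.7, 521.9),
  (8101.4, 1183.4), (10043.8, 911.0) mm³ for repair / chronic tear /
  control, truncated at zero (truncation shifts the control FTMP mean up
  by ≈ 0.08 %; tests allow for it). Muscle wet weight is volume × 1.08
  mg/mm³ with 3% lognormal scatter, chosen so the weight–volume rank
  correlation is strong (≈ 0.9), matching the observed tight
  weight–volume agreement.
* **Sections.** Synthetic stained sections paint non-overlapping red
  droplets (disks, then single pixels) until the lipid pixel count
  equals the target fraction exactly, on an eosin-pink background with
  ~1% blue nuclei speckle. The color palette is constructed so droplet
  pixels always satisfy the default HSB lipid windows and background and
  nuclei never do; recovery by the histology pathway is therefore exact
  on phantoms, and the ±0.6-percentage-point acceptance band is consumed
  entirely by packing granularity at small image sizes.

What passing on phantoms shows: the chain is algebraically correct
(thresholding, counting, spacing handling, statistics) and its failure
mode under boundary mixing has the expected sign. What it does not
show: robustness to bias fields, susceptibility artifacts, motion,
imperfect ROIs, stain variability or real infiltrate morphology — none
of which the generator models.

## Histology quantification

Lipid: a pixel is lipid iff hue ∈ [0°, 25°] ∪ [335°, 360°), saturation
≥ 0.30 and brightness ≥ 0.20 in HSB. The color space is standard for
this assay but published thresholds are not; these defaults are
explicit, configurable, and echoed into every report. Muscle: the green
channel (eosin absorbs green, so fibers are dark) binarised by Otsu by
default, with pixels at or below the threshold counted as muscle; a
constant channel is flagged "no contrast" with fraction 0 rather than
guessed. Fractions are percentages of all analysed pixels, so fat is
fat / total area; fat / (fat + muscle) can be derived from the reported
columns. Specimen values are plain means over all retained section
reads (the protocol is 10 sections read twice).

## Statistics

Spearman uses mid-ranks and the large-sample two-sided t approximation
(no exact small-sample p). The reliability statistic is ICC(2,1) —
two-way, absolute agreement, single measurement — computed from the
mean-square decomposition, with the variant tag carried in the result;
other variants are intentionally not silently selectable. ANOVA is the
standard one-way decomposition; post hoc contrasts are pooled-variance
two-sample t tests with Bonferroni multiplication over all pairs (3 for
3 groups), capped at 1.

## Pipeline conventions

`run_study` checks every referenced path before computing, excludes
failing specimens with a logged reason, continues while every group
retains ≥ 1 specimen, and records per-group remaining counts plus
whether the 5-per-group power minimum holds. Reports are deterministic
under a fixed config and seed (timestamps are confined to the log). In
the demo study the histologic per-specimen truth is 1.8 × true FTMP
plus N(0, 0.5) scatter — an affine plausibility link reflecting that 2D
histologic fat fractions run higher than volumetric FTMP — or exactly
the radiologic truth with `histology_from_truth=True`, which the tests
use to verify rank-perfect agreement between the two arms.

## Problem sizes and numerical choices

The test suite runs phantoms at 40×40×10 with ellipsoidal ROIs (~4000
voxels), sections at 96–160 px squares, oracle sweeps at ≤ 20×20×10 over
100 seeds, and the power check as 200 simulated cohorts drawn at the
cohort generator's parameter level (n = 6/group) — the noiseless
measurement chain reproduces those draws exactly, so simulating at the
parameter level is equivalent to rendering volumes and keeps the suite
fast. Demo studies run full-scale (~10⁴ mm³ ROIs, ≈ 3 × 10⁵ voxels per
specimen). Intensities are float64 throughout regardless of on-disk
type; volumes are written as NIfTI-1 with a diagonal affine; label maps
use integer codes {0 background, 1 muscle, 2 fat, 3 unclassified} with a
JSON sidecar.

## Known limitations

Single-coil, single-protocol intensity model with no transferability of
thresholds; 2D histology compared against a 3D measurement; the phantom
partial-volume model is linear single-interface mixing only; the
dispersed/clustered patterns are not calibrated to tissue; DICOM import,
GUI interaction and learned segmentation are out of scope.
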