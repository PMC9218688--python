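# Methods

## What the pipeline models

A freehand 3D shear-wave-elastography (SWE) tendon assessment: a linear
transducer is swept over the patellar tendon while an optical tracker records
its pose; the device's 2D shear-wave-velocity (SWV) maps and B-mode frames
are projected into world space and compounded into voxel volumes; the tendon
is segmented, split into proximal / mid-portion / distal regions by cuts
10 mm from each insertion landmark, and summarized by regional mean SWV;
subject-level regional values feed linear models comparing a heavily loaded
athlete group (elite alpine skiers) against healthy controls.

No real scans ship with the package (the study data it emulates are access
restricted); a digital phantom and a cohort simulator provide controlled
ground truth for every stage.

## Phantom and sweep simulation

The phantom is an elliptical-cross-section tube (default half-axes
12 × 2 mm, field-typical tendon width/thickness) around a straight
centerline between the two insertion landmarks, 46 mm apart by default. An
optional single bow parameter curves the centerline; the default is
straight. The SWV field is piecewise constant: one value per region
(defaults 9.5 / 9.0 / 10.0 m/s) on a 2.0 m/s background. The non-zero
background is deliberate — mask leakage becomes visible as bias instead of
vanishing silently. A 20° knee-flexion posture in the emulated protocol is
acquisition metadata, not something the phantom models mechanically.

A sweep is a sequence of frames with nominal poses stepping transversely
along the tendon axis (the real protocol's frame count and overlap are not
public; 96 frames over the tendon plus 3 mm margins is the package default).
Per frame, pose noise is an isotropic random rotation (SD in degrees, default
used in examples 0.5°) plus Gaussian translation jitter (0.5 mm); per pixel,
SWV gets additive independent Gaussian noise (0.5 m/s in examples, a typical
device-level repeatability scale) clipped to physical bounds (0.5–16 m/s),
and B-mode gets tendon/background intensities plus noise. Pixel centers (not
corners) define positions; the frame plane is the x–y plane of the probe
frame. Everything is deterministic given the seed; noise draws for the pose
are made whether or not the SDs are zero, so zero-noise runs consume the
same stream.

No acoustic or speckle physics is simulated: passing tests show the
*geometry and statistics* chain is correct, not that a real device's SWV
maps are unbiased.

## Compounding

Forward splatting with a Gaussian kernel in pixel-to-voxel-center distance:
σ = voxel spacing (0.5 mm default), truncated at 2σ. Invalid SWV pixels
(NaN, the device-void marker) are skipped for the SWE volume but still
contribute to B-mode. Voxels whose accumulated weight is ≤ 1e-12 are
undefined (NaN) and stay undefined — no interpolation, so regional means
never include invented data. Finalization (Σwv/Σw) is idempotent; frame
order affects results only through floating-point associativity (tested
< 1e-6 m/s).

Consequences worth knowing:

- Constant fields are reconstructed exactly (a weighted mean of a constant).
- Every defined voxel lies within the range of its contributing pixels.
- Voxels within one truncation radius of the tendon surface or of a region
  cut blend neighboring values (partial-volume). Accuracy statements
  therefore hold on the interior: the recovery tests use a ground-truth mask
  inset by 1.25 mm (just over the 1 mm truncation radius) and exclude a 1 mm
  margin around the cut planes. With zero noise the interior plateaus are
  recovered to < 0.05 m/s.

## Regions and segmentation

Cuts are planes perpendicular to the straight landmark-to-landmark axis
(cut orientation is otherwise unspecified in the emulated protocol; this is
the simplest geometry consistent with "distance from the insertion").
Voxels exactly on a cut belong to the end regions (deterministic
tie-break). The "overall" value is the mean over all defined masked voxels
(equivalently the count-weighted regional mean); the alternative — the
unweighted mean of the three regional means — is not used.

`segment_bmode` is a convenience stand-in for manual segmentation:
threshold (default: midpoint of the robust intensity range) + largest
connected component; landmarks are the centroids of the half-voxel end slabs
along the component's principal axis, with the lower-projection end labeled
proximal by convention. On the noise-free phantom it reaches Dice > 0.95
against the rasterized truth and localizes landmarks within 2 mm. Real
landmark placement was manual in the emulated study; here landmarks are
inputs (phantom truth or user JSON).

## Cohort simulator

Two groups (control/skier) with fixed sizes and sex counts; demographics are
independent per-group Gaussians (only marginal mean ± SD are reported for
the emulated study; correlations are not modeled). BMI is derived, never
drawn. Regional SWV follows a linear model with 0/1 indicators
(female = 0 / male = 1, control = 0 / skier = 1), optional per-group sex
effects, optional age and tendon-length terms, and Gaussian residuals
clipped to physical bounds.

The default parameterization (`reference_cohort_params`) encodes the
emulated study's structure: 38 controls (20 F) / 30 skiers (14 F); control
marginal mean 8.9 m/s in every region (per-region means were not reported;
flat is the documented choice); regional skier effects 1.184 / 1.401 /
2.202 m/s (proximal / mid / distal) with tendon-length slopes 0.054 / 0.045
m/s·mm⁻¹ retained where reported; male-sex effects only within skiers
(0.927 / 1.080 / 0.035 m/s) — the sex effect appears only under heavy
loading. The residual SD is the pooled within-group SD of the reported
group SDs (1.32 m/s, n = 30; 1.59 m/s, n = 38 → 1.477 m/s), used for all
regions.

`swv_overall` handling: if the model map contains an `overall` entry it is
drawn directly from that model; otherwise it is derived as the
10 : (L−20) : 10 length-weighted mean of the regional draws. The default
parameterization draws it directly, with the male-sex effect set to the
10 : 26 : 10 length-weighted mean of the regional skier sex effects
(0.820 m/s) and the group effect calibrated to 1.5 − (16/30)·0.820 =
1.063 m/s so that the marginal skier/control means are exactly 10.4 and
8.9 m/s given the sex composition. The length-weighted regional group
effects alone would imply a larger marginal gap (~1.53–1.97 m/s depending
on sex handling), so pinning the reported marginal means requires this
direct overall model; both routes are available and tested. Tendon length
(46 ± 4 mm) and CSA (100 ± 15 mm²) are field-typical values chosen once —
neither is reported for the emulated cohorts.

## Inference layer

- **OLS** by normal equations, intercept always included; SEs from the
  residual variance and inverse Gram matrix; adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1). Rank deficiency raises an error naming the
  first offending column. statsmodels is used as an independent cross-check
  in the tests, never as the implementation.
- **Leave-one-out predictive R²**: 1 − PRESS/SStot with PRESS from the
  leverage identity e_i/(1−h_ii); equals literal refit-per-left-out-point
  exactly (tested to 1e-10). A leverage of 1 is flagged as undefined.
- **Best-subset selection** enumerates all subsets of ≤ 12 candidates
  (including intercept-only) under either criterion — full-data adjusted R²
  (default, following the emulated analysis's "maximum adjusted R²"
  parenthetical) or LOO-PRESS predictive R²; the two conflate in the
  emulated description, so both are implemented and selectable. Ties break
  toward fewer predictors, then lexicographically. Note a behavioral
  asymmetry the tests pin down: with pure-noise candidates, adjusted R²
  admits a lone predictor whenever its |t| > 1 (~32% each), so
  intercept-only is only the modal choice, whereas LOO-PRESS selects
  intercept-only in a clear majority.
- **t tests**: Welch by default (the emulated analysis does not state
  pooling); Student available. Degenerate inputs (n < 2, zero variance in
  both groups) are flagged, not silently passed.
- **Regional deltas**: per-subject distal−mid and proximal−mid differences,
  compared between groups by t test (an interaction term in a joint model
  would be the alternative formulation; not implemented). Common group
  shifts cancel exactly in the deltas.
- Candidate pools: whole population {group, sex, age, weight, height, BMI,
  tendon length, CSA}; within-group models drop group. Within-group models
  use the same selection procedure with the reduced pool. No
  multiple-testing correction is applied (matching the emulated analysis's
  unadjusted p-values at α = 0.05).

## Problem sizes and numerical choices

The shipped defaults are desk-scale: 96–112 frames of ~14–24 × 56–64 px at
0.5 mm, 0.5 mm voxels (~2·10⁵ voxels), cohorts of 68. Monte-Carlo recovery
uses 200 cohorts for group means and 500 per coefficient, each checked
within 3 Monte-Carlo SEs of the generating value; t-test calibration uses
10⁴ null replicates (rate within 1.5 percentage points of 5%). Weight
epsilon 1e-12 defines "undefined"; poses are validated orthonormal to 1e-6
on file read (full-precision round-trip) and 1e-6 at construction; SWV
bounds 0.5–16 m/s clip both simulator outputs (clipping probability is
negligible at the default parameterization, < 1e-4 per draw).

## Known limitations

- The phantom's piecewise-constant field and noise-free geometry make
  recovery tests necessary but not sufficient evidence for real tissue:
  speckle, anisotropy, fiber-misalignment artifacts and scan-conversion are
  not modeled.
- Demographic covariates are independent within group; real weight–height
  correlation is absent (configurable in principle, default 0).
- Reported between-group p-values of the emulated study depend on its
  restricted raw data and are not reproduction targets; only generative
  parameters and their unbiased recovery are.
- The segmentation helper assumes a bright tendon on a dark background — a
  phantom convention, not a property of clinical B-mode.
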