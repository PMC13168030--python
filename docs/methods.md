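# Methods

This note documents the measurement model, the simulator the tests rest
on, the numerical choices, and the limits of what the test suite can show
about field data.

## Measurement model

**Geometry.** The camera is an ideal pinhole: no lens-distortion model.
Pixel coordinates are 0-based, origin top-left; pixel *x* is the image
column (cross-track), pixel *y* the row (along-track, the platform travel
direction). A pixel (*x, y*) with depth *z* back-projects to camera
coordinates *X* = (*x−c_x*)z/f_x, *Y* = (*y−c_y*)z/f_y, *Z* = z. Plant
spacing is the full 3D Euclidean distance between adjacent keypoints, so
height differences between neighboring plants contribute to the measured
spacing — by design, since that is the physical keypoint-to-keypoint
distance.

**Frame alignment.** RGB and depth streams free-run at configurable rates
`rgb_rate`/`depth_rate`; RGB frame *t* uses depth frame
⌊t·f_depth/f_rgb⌋. The rates are config values (hardware documentation for
this class of rig quotes both 15 and 30 fps depending on mode); the
geometry is rate-agnostic.

**Depth extraction.** The median of the valid pixels in an odd-sided
window (default 3×3) centered on the anchor pixel, clipped at image
borders (padding would fabricate depth). Invalid pixels (raw value 0 or
NaN) are removed before the median and can never influence the result.
An empty valid set yields MISSING: that detection contributes no 3D
observation in that frame, and the track relies on its other frames. The
anchor defaults to the detected keypoint (`depth_anchor="keypoint"`)
because the back-projected point *is* the keypoint; sampling depth at the
bbox center while back-projecting the keypoint would mix two parallax
lines. The bbox-center anchor remains available as a config switch for
comparison with systems that sample there.

**Tracking.** Identity maintenance uses a motion-only greedy
nearest-neighbor tracker: each detection's camera point is shifted into
world coordinates by adding the platform displacement at its frame to the
along-track coordinate, and matched one-to-one to the nearest live
track's running world position within a metric gate (default 0.5× target
spacing). Unmatched detections open tracks; tracks unmatched for more
than `max_age` frames (default 5) close. Appearance-embedding
re-identification, Kalman prediction and fused Mahalanobis/cosine costs —
the machinery of full appearance-based trackers — are deliberately out of
scope: with a static scene and known ego-motion, world-frame gating
already pins identity, and the contract the downstream statistics need
(one track per plant, no switches) is what the tests verify. All
tie-breaks are deterministic (ascending distance, then track id, then
detection order), so runs are bit-reproducible.

**World aggregation.** A track's position is the coordinate-wise median
of its world observations (mean available via `aggregate="mean"`). The
median is robust to isolated depth failures and the occasional
mis-association that inflates per-frame scatter.

**Rows.** Row assignment is 1D gap clustering on the world cross-track
coordinate (new row when the gap to the previous track exceeds `row_gap`,
default 0.30 m), with members ordered along-track. Clustering in world
coordinates rather than per-image strips makes the partition independent
of the viewpoint; the per-frame strip picture is the same idea seen from
one frame.

**Quality indices.** See README for the formulas. Two deliberate
interpretation points, both flagged in the report's provenance:

* The multiples count is *n₂ = n′₁* (the count of ratios ≤ 0.5). This is
  the only assignment under which *n₁+n₂+n₀ = N′* holds identically, and
  hence QFI+MUL+MI = 100% — a conservation property the evaluation relies
  on and the test suite enforces.
* σ is the population standard deviation of the qualified ratios about
  their mean. The raw second-moment form √(ΣS_i²/n′₂) (an RMS) is kept
  behind `sigma_formula="as_printed"` for auditing only: for ratios near 1
  it returns ≈1, i.e. a "CV" of ≈100%, which measures magnitude, not
  dispersion. CV = 100·σ by default (the qualified-ratio mean is ≈1 by
  construction, so this matches the classical σ/mean definition to second
  order); `cv_normalize_by_mean=True` selects 100·σ/S̄.

Bin boundaries are closed above: a ratio of exactly 0.5 is a multiple,
1.5 qualified, etc. A stand so dominated by short intervals that n₁ < 0
is reported unclamped with `valid=False` — clamping would hide a
pathological stand.

## The simulator

`synthetic_field` emulates the acquisition the pipeline was designed for:
drop points every `target_spacing` along each row; each point missing with
`p_miss` (consecutive misses lengthen the surviving gap — a gap of ~2×
target binning as one miss, matching the index semantics), doubled with
`p_multiple` (the extra plant offset by N(0, `multiple_offset_sd`²),
creating the short gap a multiple produces), and scattered along-track by
N(0, `spacing_sd`²). Defaults: 101 drop points (the calibration layout's
population per spacing), 0.20 m target, 0.008 m placement scatter,
0.03 m multiple offset, 0.15 ± 0.02 m plant height (five-leaf stage),
camera 1.15 m over the ground moving at 0.556 m/s (2 km/h). The rendered
sensor defaults to the rig's 1100×620 frame; tests and the acceptance
script use `DESK_INTRINSICS` (256×144, same frustum) and 3–5 fps so a
full survey renders in seconds — the geometry is resolution- and
rate-agnostic, and unit tests cover the full-size intrinsics.

Sensor imperfections: Gaussian keypoint jitter (px), Gaussian per-pixel
depth noise (m), independent per-pixel dropout (invalid = 0 in the PGM),
and millimeter quantization of the depth file. The noisy-scenario values
used in tests (0.5 px jitter, 0.012 m depth noise, 2% dropout) match the
~1–1.5% depth error a stereo camera quotes at 1.15 m range.

Ground-truth spacings are the 3D Euclidean distances between adjacent true
keypoints — exactly the quantity the pipeline reconstructs — and the
oracle quality report is computed from them by the same evaluator
(`oracle closure` is tested). Two independent random streams (stand
layout vs. acquisition noise) are sub-seeded separately so changing sensor
noise never changes the stand.

**What the simulator does not model**, and therefore what passing tests do
not show about field data: appearance (no RGB rendering, so detector
errors beyond jitter/confidence are not exercised), leaf occlusion
(modeled only implicitly — near-coincident plants can be merged by NMS),
weeds and background clutter, platform pitch/roll and vibration, ground
micro-topography (the ground plane is flat), and correlated depth error
(noise is i.i.d. per pixel, real stereo error is spatially structured).
Recovery results on synthetic runs bound the pipeline's geometric and
statistical error, not the detector's.

## Numerical choices

* Depth files are integer millimeters; all computation is in meters.
* Depth-window centers round to the nearest pixel; windows clip at
  borders.
* The quality evaluator is exactly scale-free — it depends on spacings
  only through the dimensionless ratios. Note that rescaling the *inputs*
  (d·f, d_ref·f) in floating point perturbs them by an ulp unless f is a
  power of two; the invariance tests therefore assert bitwise equality
  over representable factors and count-identity plus 1e-12-relative
  statistics otherwise.
* CSV floats are written with 9 significant digits; presentation rounding
  (2 decimals) happens only in the `report` CLI verb.
* Degenerate inputs: an empty spacing series or N′ = 0 raises an
  evaluation error rather than returning indices with no support; a row
  with fewer than two plants yields an empty spacing series with a logged
  notice; an all-invalid depth window yields MISSING rather than a guess.

## Problem sizes

The test suite and acceptance script run surveys of 12–500 drop points
rendered at 256×144 and 3–5 fps (hundreds of frames, thousands of
detections); the stochastic-recovery check compares 20 stand realizations
of 500 points against a 100 000-position brute-force Monte-Carlo estimate
of the expected Miss Index. These sizes give the binomial standard errors
the assertions rely on while keeping a full run in seconds.

## Known limitations

* MUL is systematically under-measured when the multiple offset is small
  relative to plant size: NMS merges heavily-overlapping detections of
  near-coincident plants (field systems show the opposite bias, from
  identity switches — the motion-only tracker here does not exhibit
  those on a static scene).
* The constant-speed world transform assumes straight travel along the
  row; curved paths require the per-frame displacement table, and lateral
  drift is not compensated.
* Per-row vs. pooled evaluation can differ when rows have few intervals;
  both are reported.
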