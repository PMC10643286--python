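# Methods

This note documents the models, estimators and numerical choices behind
`stereoflight`, and what the synthetic-data validation does and does not
establish.

## Coordinate conventions

All positions are in mm, speeds in m/s, angles in degrees wrapped to
(−180°, 180°], positive counter-clockwise seen from above. The analysis
frame is defined by the scene: water plane = XY (normal +Z, oriented toward
the flight), sun azimuth = +X, water-contact point = origin, t = 0 at first
water contact. **Altitude is contact-referenced**: the origin sits at the
lowest CoM position of the landing, roughly half a body height above the
water film, and every altitude statistic (including the 10 mm landing
threshold) is measured from there. The synthetic generator calibrates its
targets in the same convention.

## Synchronisation

The 25 Hz Gray-code counter repeats each value for `frame_rate / 25` frames
(10 at 250 fps). LED traces are binarised per channel at the midpoint
between the two intensity modes (1-D two-means); a channel is excluded when
its mode separation does not exceed four times the within-mode spread —
high counter bits simply never toggle within a few-second clip, and a noisy
constant channel must not be split into fake modes. Excluded channels are
zeroed identically in both cameras, which leaves the alignment unchanged.
The offset maximises the fraction of frame-wise equal counter values; the
confidence ratio compares the best peak with the best score *outside* one
counter period, because lags within a period share ~90% of frames. Accuracy
is one frame by construction; sub-frame interpolation is not attempted.

## Stereo reconstruction

The 11-parameter DLT is solved as a homogeneous linear system with
Hartley-style centring/scaling of world and pixel coordinates (conditioning
only; results are de-normalised). Coplanar calibration targets leave a
3-dimensional solution family and are rejected via the second-smallest
singular value. Reprojection RMSE is reported per coordinate, so it is
directly comparable to the pixel noise level. Triangulation solves the four
ray-constraint equations for three unknowns by least squares (batched normal
equations); per-sample residuals and condition numbers are kept for quality
control. No lens-distortion model is used. With two cameras ~1.2 m from the
scene and 1 px digitisation noise, the median 3D error is ≈1–2 mm inside the
calibrated volume and grows toward its edges — the same failure mode real
checkerboard calibrations show at the image periphery, which is why the
synthetic calibration spreads board poses across the filmed volume.

## World alignment

Rotation 1 is the minimal rotation carrying the fitted plane normal onto +Z
(axis n × ẑ — unique, introduces no roll); rotation 2, about Z, carries the
XY-projection of the shadow vector onto −X. The angle between the shadow and
its projection is reported as a reconstruction-quality metric (near 0° on
clean data). t = 0 is automated as the first *descending* sample of the
below-threshold altitude excursion that contains the global altitude
minimum; anchoring at the minimum makes the rule immune to spurious
low-altitude dips far from the water (reconstruction tilt at the volume
edges), and a `t0_frame` override preserves the manual workflow. The
translation subtracts the lowest filtered-CoM point in a window spanning
from 20 ms before t = 0 to 20 ms past the altitude minimum: the threshold
crossing *precedes* the actual touch-down, so a window closed at t0 + 20 ms
would miss the on-water stretch. The t0 search and the translation both use
the low-pass-filtered CoM so single noisy samples cannot define the origin.

## Kinematics

Filtering is a second-order Butterworth at 100 Hz applied forward and
backward (zero phase): any phase lag would bias every t0-relative timing,
most visibly the descent onset. End effects are handled with anti-symmetric
(odd) reflection padding, which extends a trajectory's local trend instead
of folding it back. Up-sampling (factor 3) uses a cubic spline, preserving
the original samples exactly; derivatives are central differences at
dt = 1/(f_s·F_up). Bearing is undefined (NaN) below a horizontal-speed floor
of 0.05 m/s rather than amplified noise; such samples break straight
segments.

**Curvature.** r_κ = (x′² + y′²)^{3/2} / |x′y″ − y′x″| with central
differences, radius capped at 10⁶ mm on locally straight paths. The second
derivative of a 100 Hz-bandwidth track is noise-dominated at any realistic
pixel noise (the noise variance of a differentiated band-limited signal
grows with the cube of the bandwidth), so the path is additionally smoothed
with a zero-phase 2nd-order Butterworth before differentiating. The default
cut-off of 12 Hz was chosen from the classification margin: body saccades
(~30 mm turn radius, an order of magnitude below the 210 mm straightness
threshold) survive smoothing as sub-100 mm curvature events, while gentle
inspection arcs (≥400 mm) stop dipping below the threshold through noise.
The cost is that each saccade's below-threshold footprint widens by a few
tens of ms.

## Segmentation

The strict landing is the contiguous altitude < 10 mm window containing
t = 0; the flight-analysis landing additionally includes the descent, whose
onset is the latest pre-contact crossing of 20% of the vertical-velocity
curve's peak negative value. Per flight, the vertical velocity is smoothed
at 20 Hz before thresholding (differentiation noise would otherwise set the
"latest crossing"); in cohort-mean mode the crossing is read off the
cohort-mean curve restricted to time points where at least half the flights
still contribute, since the tails of the mean curve are a couple of noisy
flights. Straight segments are maximal runs with r_κ above threshold and a
defined direction, intersected with the phase windows; runs shorter than
10 ms are dropped. Approach/departure segments carry bearing-based
directions; landing segments heading-based ones (during the landing reversal
the body yaws ~180° while the bearing is retained, so bearing stops tracking
where the animal points). Segment weights are the un-normalised resultant
lengths of the summed unit direction vectors: longer, more directed segments
count more.

## Circular statistics

The MMR statistic ranks segment lengths ascending (mean ranks for ties) and
computes R* = |Σ rankᵢ (cos θᵢ, sin θᵢ)| / n^{3/2}. The null distribution is
sampled by Monte Carlo — uniform angles, the observed rank multiset kept
(sorted, so the p-value is invariant to segment order) — with
p = (1 + #{null ≥ observed}) / (1 + n_mc). A Monte-Carlo null is exact for
the small, tie-prone segment counts here; the published critical-value table
(1.048 at n = 10, α = 0.05) and the asymptotic tail P(R* > r) = exp(−3r²)
serve as independent cross-checks in the tests. Axial preferences are tested
by doubling the angles modulo 360° with unmodified lengths as weights,
re-ranked within each phase's segment set. The Wilcoxon signed-rank
comparison of approach vs departure uses the exact null for ≤25 untied
pairs and the normal approximation with continuity correction otherwise;
all-zero differences give p = 1. Quartiles use linear interpolation.

## The synthetic-flight generator

The generator emulates the behavioural sequence, not the aerodynamics:
phases are spline/arc templates.

* **Approach** (default 1.5 s pre-contact): the fly orbits the tray —
  gentle arcs (800 mm nominal radius, with a homing term capped at a 400 mm
  turn radius that keeps the loops inside the filmed volume) interrupted by
  Poisson-placed body saccades (2 s⁻¹, 60° yaw at a 30 mm radius, ~20 ms).
  Only saccades break the straightness criterion. Altitude follows a linear
  trend (clamped clear of the landing threshold) plus 2.5 Hz bobbing whose
  amplitude is solved so the mean vertical speed matches its per-flight
  target; the total 3D speed is held constant per flight (horizontal speed
  absorbs the bobbing), so the per-flight mean total speed equals the
  sampled value by construction.
* **Descent**: vertical velocity v_pk·s(τ) with a unit shape that rises as
  sin², peaks at 75% of the descent and brakes to 55% of peak at touch-down
  (field mean curves recover toward zero before contact; an interior peak
  also keeps the 20%-of-peak onset crossing on the clean rising flank).
  The descent duration is solved per flight so the clean 20% crossing leads
  t = 0 by exactly the configured 135 ms; with the default −0.45 m/s peak,
  20% is −0.09 m/s. The heading reverses by 180° (smoothstep) while the
  bearing is retained, and the pitch ramps to +40°.
* **Contact**: the vertical velocity blends linearly to zero over ~12 ms
  (an abrupt kink would ring through the zero-phase filter and bias the
  altitude reference), then the CoM drifts flat at 0.3 m/s, 5 mm above the
  water. The duration of the *below-threshold window* — what the strict
  landing definition actually measures, and what the published 73 ± 11 ms
  refers to — is calibrated to a normal draw by solving for the flat time
  after accounting for the descent tail and climb head.
* **Departure**: a straight climb at per-flight horizontal and vertical
  speeds with a ~16 ms cosine onset ramp; its duration is solved so the mean
  altitude over the measured departure phase (everything after the strict
  landing) equals the per-flight target.

Per-flight speeds and altitudes are drawn from log-normal distributions
matched to the published medians and quartile *ratios* (the published
quartile pairs are not exactly log-symmetric, so individual quartiles match
to ~2%). In cohort mode the draws are **stratified**: each parameter uses an
independently permuted grid of quantiles (i + 0.5)/n, so the cohort carries
the target distribution's quantile structure exactly and its median
estimates the calibration median without √n sampling error — the right
property for a calibration cohort. Camera placement follows the field setup
(two views ~90° apart, 1.1–1.2 m from the tray, 1920×1080, with per-recording
jitter); the camera distance backs off automatically for unusually wide
flights, standing in for the experimenter framing the scene. Checkerboard
calibrations (5 poses spread over the filmed volume, 0.3 px noise) are
expressed in a random rigid "calibration frame" so the alignment stage does
real work. Pixel noise is 1 px i.i.d. per keypoint (a fly is only ~25 px
long in these views); the LED counter, the inter-camera offset (17 frames)
and the observer azimuth are all regenerated per recording.

## What the validation shows — and what it does not

The synthetic cohort validates the *pipeline*: with the generator's defaults
the recovered cohort medians sit within a few percent of the generator truth
(approach total speed carries a +2–3% bias — the mean of |v + noise| exceeds
|v|; at 1 px noise and this geometry the velocity noise after 100 Hz
filtering is ≈0.2–0.3 m/s per axis), the cohort-mean descent onset lands
within ~5 ms of the configured −135 ms, and the measured time below the
landing threshold reproduces the calibrated 73 ms. The measured strict
landing can overestimate the generator's window by ~10 ms at high noise
because the altitude reference is a minimum statistic of noisy samples —
the field analysis notes the same overestimation with the same definition.

The generator does **not** emulate: digitisation outliers or dropped frames
(real DLC output needed manual correction), wing or roll kinematics (two
tracked points cannot constrain roll), wind, lens distortion, or any
coupling between flight direction and the sun — directions are drawn
uniformly, so the directional tests are validated for calibration
(size ≈ 5%, axial power) rather than against a known preference. Passing
tests therefore show the measurement chain is unbiased at realistic noise,
not that real horseflies behave like the templates.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| frame rate | 250 fps | field cameras |
| Butterworth cut-off / order | 100 Hz / 2, zero phase | published filtering |
| up-sampling factor | 3 | published F_up |
| contact threshold | 10 mm CoM altitude | ~half a body length |
| descent-onset rule | 20% of peak negative v_z | published definition (−0.09 m/s) |
| straightness threshold r_κ | 210 mm (105/320 sensitivity) | published criterion |
| minimum segment duration | 10 ms | published exclusion |
| bearing speed floor | 0.05 m/s | direction meaningless slower |
| curvature pre-smoothing | 12 Hz zero-phase | saccade/straight classification margin |
| onset v_z smoothing | 20 Hz | crossing must not be set by noise |
| MMR null replicates | 10 000 | p resolution ~10⁻⁴ |
| cohort size | 66 flights | usable field events |
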