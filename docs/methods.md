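# Methods

## The walkway model

A walkway test observes one bird crossing a straight corridor (~3 m)
under a fixed top-view camera at 11 frames/s. After geometric correction
the walk axis is the image x axis and the corridor width the y axis. The
analysis models the bounding-box centre as

    y(t) = m(t) + e(t),

where `m(t)` is a smooth *movement trajectory* — the path the bird is
actually following, not necessarily straight — and `e(t)` is the lateral
oscillation of the centre of gravity as weight shifts onto the supporting
leg at each step. `m` is estimated as a least-squares 5th-order
polynomial in the frame index; the residuals estimate `e`. Three scalar
features follow: mean |residual| (lateral body oscillation, px), the
number of residual sign changes (step count: two trajectory crossings per
left–right stride pair), and frames/fps (completion time, s). The
bounding-box length-width ratio is carried as a per-frame series; sudden
drops were once hypothesized to flag wing support, but the signal is not
specific (wing flaps, shakes and turns look the same), so no feature is
derived from it.

Preprocessing order is fixed and asserted by a regression test:
**mask → interpolate → smooth → fit.** Frames where the head keypoint is
not forward of the box centre along the walk direction are masked (the
bird turned around; a tie counts as forward so masking stays
conservative). Masked runs of ≤ 5 frames are linearly imputed; a longer
internal run excludes the bird from feature output rather than inventing
half a second of data; masked endpoints are trimmed. Smoothing is a
centred window-3 moving average whose window truncates at the series ends
(no padding).

### Numerical behaviour of the quintic detrending

Because the residuals of a least-squares quintic are orthogonal to all
polynomials of degree ≤ 5, they change sign at least 6 times whenever
they are not identically zero, and the fit absorbs a small part of the
oscillation signal itself. Both effects vanish as the number of
oscillation cycles in the walk grows: the mean-|residual| deficit against
the analytic value 2A/π of a sinusoid of amplitude A is ≈ 5% at 5 cycles,
1.6% at 10 and 0.4% at 20; boundary fit error can add or remove 1–2
crossings at study-scale walks (~7–11 cycles) and disappears by ~25
cycles. Tests therefore assert exact crossing recovery in the many-cycle
regime, a ≤ ±2 crossing tolerance at study scale, and the 2A/π value at
20 cycles × 500 samples/cycle. A window-3 moving average attenuates a
sinusoid of frequency f by the known gain (1 + 2cos(2πf/fps))/3; the
synthetic generator compensates amplitudes by exactly this factor.

Residual zeros inherit the previous nonzero sign (leading zeros take the
first nonzero sign) so a tangential touch of the trajectory counts as one
crossing, not two. Completion time uses the frame count from first to
last detection inclusive, n/fps. The trajectory is fitted against time by
default; fitting against the longitudinal coordinate is available
(`fit_against="position"`) since a path plotted in the x–y plane is an
equally defensible reading.

## Geometry

Calibration renders or ingests views of a 6×6-square checkerboard
(41.1 cm across, i.e. 6.85 cm squares). Inner corners (5×5) are located
by a quadrant-kernel saddle response, refined to sub-pixel, and ordered
by mapping the unit grid projectively onto the four extreme corners.
Zhang's method gives closed-form intrinsics from per-view homographies;
a full nonlinear reprojection minimisation then refines intrinsics,
distortion and per-view poses. Only one radial coefficient (k1) is
estimated by default: over the radial range a centred board covers, the
r⁴/r⁶ terms are nearly collinear with k1 and fit corner noise rather
than the lens (`radial_terms=2|3` enables them). Undistortion resamples
each output pixel from its forward-distorted source position bilinearly.

Rotation alignment converts a frame to grayscale, applies Canny
(thresholds 50/150 on the 8-bit range — unremarkable defaults for
high-contrast walls), and a probabilistic Hough transform. Among
segments at least 40% of the frame width long and within 45° of
horizontal, the one whose midpoint lies lowest is taken as the lower
corridor wall; its orientation is refined by a total-least-squares fit to
the nearby edge pixels. The frame is rotated by α = θ − 90° (θ the
normal-form line angle), filling out-of-bounds pixels with the frame
median so the rotation itself does not manufacture long border edges for
a subsequent detection pass. One global rotation per session or one per
frame are both supported; the pipeline applies one per frame.

## Detection evaluation

Single-class detections are matched to annotations greedily in descending
confidence, each truth claimed at most once, a prediction counting as TP
iff its best unmatched IoU reaches the threshold. AP is the 101-point
interpolated area under the precision envelope (the mAP50-95 convention),
averaged over IoU thresholds 0.50:0.05:0.95 for mAP50-95. Head keypoints
are scored on box-matched pairs with a radius of 0.1 × the truth-box
diagonal — a stand-in rule, since no per-keypoint OKS sigma exists for a
chicken head; the tolerance is configurable and a sweep of it is
monotone by construction.

## Statistics

* Pearson correlations carry Fisher-z confidence intervals and t-based
  two-sided p-values.
* The r×c Fisher exact test enumerates every table consistent with both
  margins and sums the probabilities not exceeding the observed table's
  (relative tie tolerance 1e-7, the convention of mainstream exact
  tests); the enumeration is validated on every call by checking the
  probabilities sum to 1 within 1e-10. Totals above 500 require the
  seeded Monte-Carlo mode.
* Each feature model is OLS with a class factor, body weight as
  covariate, and their interaction, which is dropped when a partial
  F-test on the whole interaction block gives P > 0.05 (per-coefficient
  t-tests would be ambiguous with 3 levels). LS means are model
  predictions at the sample-mean weight; pairwise p-values use the
  studentized-range distribution with k groups and the residual df.
  Significance is annotated at P ≤ 0.05 with a tendency band up to 0.10.
* K-means runs on z-standardized features (raw scales would let
  completion time dominate) with k-means++ seeding and 10 restarts, best
  inertia kept. Clusters are relabelled by mean completion time —
  A fastest, B slowest, C intermediate — so labels are comparable across
  seeds; the confusion matrix reports counts and within-GS-class
  percentages.

## The synthetic generator

`simulate_population` emulates the study cohort: GS classes drawn with
probabilities 0.602/0.322/0.076, body weight N(2235/2350/2480 g, 235 g)
per class, leg-health classes drawn *independently* of gait class
(HB1 with p = 0.076; FPD 0.534/0.339/0.127) so the no-association null is
reproducible. Each bird walks with per-class parameters: target
completion times 7.0/8.8/21.6 s, step counts 12.6/14.7/22.4 and
oscillation 9.3/10.7/10.9 px, chosen so the extracted feature means land
near the study-scale class means. The lateral path is a cubic drift
(absorbable exactly by the quintic fit, isolating oscillation recovery
from trajectory-model mismatch) plus a sinusoid of amplitude
(π/2)·target/MA-gain and frequency steps/(2·completion), plus Gaussian
noise (SD 1 px). Pauses freeze the longitudinal coordinate while frames
keep streaming — a long completion time can mean slow walking, sitting,
or both. Backward-facing frames (p = 0.0011, the masking rate the method
expects) put the head behind the centre; 1% of frames go missing.

Within-class spread is a modeling choice the study does not pin down.
The generator uses coefficients of variation around 15% (completion SD
1.1/1.4/3.2 s per class, stride-frequency SD 0.05 Hz, oscillation SD
1.5 px): it emulates clean, voluntary walking. The study's own residual
spread is considerably larger (pooled residual SD ≈ 5 s for completion
time), plausibly dominated by handling/nudging events and observer
timing that the simulator deliberately does not model. Consequently,
passing tests show that the *pipeline* recovers class structure faithfully
from clean tracks; they do not show that class orderings of point
estimates would be stable at n = 118 under field-level noise — the study
itself could not separate GS1 from GS2 completion times significantly.
The generator also does not emulate photorealistic appearance, wing-support
events, multi-bird occlusion, or detector failure modes beyond dropped
and backward-facing frames.

## Problem sizes and tolerances in the test suite

Tests run at deliberately desk-friendly sizes: cohorts of 25–118 birds
(one 10,000-bird draw for the class-frequency law-of-large-numbers check
with shortened walks), 12–15 rendered checkerboard views at 640×480,
corridor frames at 480×360, and 100-instance AP oracle sweeps with ≤ 20
detections. Calibration asserts k1 within 10%, rotation within 0.5°,
AP within 0.01 of brute force, exact-test p-values to the printed three
decimals, and direct-formula agreement to 1e-8 for the classical
statistics. The full suite runs in well under a minute on one CPU.

## Known limitations

* Completion time counts all retained frames; whether masked
  backward-facing frames should count toward it is ambiguous — they do
  here (the bird occupies the corridor while turned around).
* The keypoint-correctness rule is a stand-in, not an established OKS.
* The Fisher test is exact but exhaustive; large tables need the
  Monte-Carlo mode.
* Crossing counts inherit ±1–2 boundary sensitivity from the polynomial
  detrending at short walks; any comparison across systems should hold
  walk length roughly constant.
* Calibration assumes a roughly frontal board (in-plane rotation well
  below 45°) when ordering corners.
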