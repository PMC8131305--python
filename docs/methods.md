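# Methods

## Problem and signal model

The measurement target is a brief, stimulus-locked displacement of the
stapedius tendon — the visible correlate of an electrically evoked
stapedius reflex (eSR) — in video of the opened middle ear. The tendon
motion rides on much larger global scene motion (heartbeat at ~1.1 Hz,
respiratory drift at ~0.25 Hz, microscope vibration) and on sensor noise.
The pipeline therefore separates three scales: global motion is removed by
registration to a static reference patch on the cochlear promontory; slow
local drift is removed by re-anchoring each tracked marker to its
pre-stimulus rest position; and the remaining fast, broadband twitch is
detected against a robustly estimated noise floor.

## Stabilization

Each frame is registered, translation-only, to the reference ROI extracted
from the first frame. Rotation and zoom are neglected: the recording
optics sit at a fixed magnification and the promontory is rigid. The shift
estimate is the normalized cross-correlation (NCC) peak over a ±20 px
search window, refined first by quadratic interpolation of the correlation
peak and then by a few Gauss–Newton iterations on the brightness-constancy
residual. The second refinement matters: parabolic interpolation alone
leaves a pixel-locking bias of a few hundredths of a pixel that oscillates
with the sub-pixel phase of the true shift — larger than the displacement
noise floor the detector works at. Frames whose peak correlation falls
below 0.5 are flagged and their shift interpolated from confident
neighbours.

A resampled (stabilized) frame stack is produced for inspection, but the
tracker does not consume it: resampling imprints a shift-dependent blur
that modulates downstream position estimates at exactly the nuisance
frequencies. Instead, markers are tracked on the original frames and the
registration shifts enter as initial guesses and are cancelled
differentially (below).

## Marker seeding (MSER)

Trackable points come from maximally stable extremal regions inside the
tendon ROI: connected components of the thresholded image whose area is
stationary across `delta = 5` threshold steps (8-bit scale), in both
polarities. Region identity across thresholds follows the position of the
region's intensity maximum; per chain, the single most stable threshold is
kept. Each region is summarised by its equivalent (second-moment) ellipse,
and markers are the ellipse centers accepted greedily in descending area
order under a 6 px minimum-separation rule, up to 8 markers. Area bounds
are 30 px to 20% of the ROI (the latter rejects the trivial whole-ROI
component while still admitting blob-scale regions in tendon-sized ROIs).

## Tracking (KLT)

Each marker is followed by iterative Lucas–Kanade solution of the
translation-only brightness-constancy equations (window 21 px, 3 pyramid
levels, convergence 0.01 px). Tracking is *anchored*: every frame is
solved against the marker's birth-frame template, with the previous
frame's displacement as the initial guess. This keeps frame-to-frame
initialisation while avoiding the random-walk drift that frame-to-frame
integration accumulates. The anchor template is a 15-frame temporal
average of stabilized frames — a single anchor frame would imprint its own
sensor-noise realisation as a constant per-marker position bias. Every
step is validated by re-tracking backwards to the template; a marker whose
backward track misses its origin by more than 1 px, or whose window leaves
the frame, is invalidated and stays invalid (with re-detection of a fresh
marker set if more than half are lost at a stimulus onset).

Global motion is cancelled differentially: a second marker set is seeded
and tracked in the reference patch, and the mean reference displacement is
subtracted from every tendon trajectory. Static template biases are common
to both terms of the difference and cancel against the baseline.

## Trajectory conditioning

Three stages run between tracking and detection, in order:

1. **Rest-position re-anchoring.** Each coordinate trace is referenced to
   the marker's rest position, estimated as the median position inside
   each stimulus's pre-onset baseline window and linearly interpolated in
   between. Measuring displacement from the *current* rest position (not
   from the track start) is what makes the nonnegative magnitude signal
   behave linearly for small twitches: a static offset vector `o` would
   otherwise fold into `|o + d·u| − |o|`, compressing the response by a
   direction-dependent factor. Anchoring only in known-quiet windows also
   guarantees the response can never leak into its own reference (a plain
   rolling median does leak when stimuli are closely spaced). Without a
   schedule, a 2 s rolling median is the fallback.
2. **Heartbeat notch.** The Savitzky–Golay filter is a low-order
   polynomial smoother: at any window short enough to conserve a ~100 ms
   twitch its suppression of a 1.1 Hz sinusoid is under 3%. The
   phase-locked heartbeat residual that survives stabilization (the
   differential pixel-locking bias of the tendon versus the reference
   texture, ~0.01 px) is therefore removed spectrally: a zero-phase IIR
   notch (Q = 5) at the heartbeat rate, estimated as the dominant
   spectral peak of the stabilizer's shift trace in the 0.7–3 Hz band.
   The notch is skipped when no clear peak exists. A broadband twitch
   loses about 8% of its peak here.
3. **Savitzky–Golay smoothing** of each coordinate trace (window 11 frames
   at 50 fps ≈ 220 ms, polyorder 3). Smoothing the *coordinates* before
   forming magnitudes — rather than the aggregated magnitude signal —
   avoids rectified-noise compression of small peaks. The filter
   reproduces polynomials up to degree 3 exactly and costs the default
   twitch peak under 2%.

The displacement signal is then the per-frame median across valid markers
of each marker's distance from rest (median rather than mean: robust to a
single glitching track). Frames with fewer than 2 valid markers are
linearly interpolated, up to 5 consecutive frames; worse coverage is an
error.

## Reflex decision

For each stimulus, the noise floor is `1.4826 × MAD` of the raw
(pre-smoothing) displacement signal over all pre-onset baseline windows of
the recording, median-subtracted per window and pooled. Pooling matters: a
single 0.5 s window of smoothed, correlated samples estimates the MAD with
~34% coefficient of variation, which alone inflates the false-alarm rate
several-fold. Measuring the floor on the *raw* signal while taking the
decision peak from the *smoothed* signal is what gives the detector its
margin: smoothing conserves the reflex peak but pushes noise peaks well
below the raw floor, so the single-sample threshold `k = 3` holds even
though the decision statistic is a maximum over the response window.

The decision statistic is the baseline-median-corrected peak of the
smoothed signal within 0.3 s after onset (twitch latency ~60 ms plus
~80 ms rise-to-peak, with margin; a longer window only inflates the
windowed maximum of noise). A stimulus is detected when the peak exceeds
`k = 3` noise floors; the peak value is reported as the motion-vector
length and its time as the latency. Sweeping levels on one electrode, the
eSRT is the lowest tested level with a detection, the dynamic range runs
from there to the highest tested level, and a non-monotone flag marks
undetected levels above threshold. No detection at any level is the
absent-reflex outcome.

## Synthetic study conditions

The generator renders a 160×120 px field (14 mm of visual field across the
width, so ~0.0875 mm/px) at 50 fps: a band-limited background texture, an
elliptical tendon (semi-axes 26×13 px) carrying ~14 Gaussian blobs as
trackable features, and a 44×44 px promontory reference patch. Background
and tendon share a similar base intensity range so the tendon rim is a
weak step — the trackable features are interior blobs, not mixed edge
bands that straddle the moving and static layers and would track with
partial gain. Global translation is rendered by exact Fourier phase shift
of the textures (band-limited, so alias-free) with the tendon mask
evaluated analytically at its shifted position; bilinear-resampled
rendering is avoided deliberately because its shift-dependent blur is an
artifact no estimator can register against, and the fidelity requirement
on the forward model is exact translation-equivariance.

Nuisance defaults: heartbeat 0.8 px at 1.1 Hz, respiration 2.0 px at
0.25 Hz along oblique directions, white camera jitter of 0.1 px SD, and
additive Gaussian sensor noise of 2.0 intensity units (8-bit scale).
Twitch defaults: logistic amplitude-versus-level law (threshold 20
stimulation units, slope 0.5 per unit, saturation 3 px ≈ 0.26 mm),
difference-of-exponentials time course with 60 ms latency, 50 ms rise and
200 ms decay constants, directed along +x. The law's logistic form is a
modelling choice — the physiology only constrains it to be thresholded,
non-decreasing and saturating.

**Twitch SNR** is defined against `sigma_t`, the robust SD of a single
marker's raw displacement fluctuation in a stimulus-free recording under
the default nuisance (~0.009 px here) — the measurement noise an
individual trajectory carries before the median-across-markers and
smoothing stages add their gain. Benchmarks calibrate `sigma_t` once per
condition from a dedicated no-twitch run.

What the generator does *not* emulate: occlusion by instruments or fluid,
illumination changes, focus drift, rotation or zoom, tendon deformation
(the twitch is a rigid translation of the tendon layer), and 3-D motion
components. Passing the synthetic benchmarks therefore demonstrates the
pipeline's numerical behaviour under the stated motion and noise model,
not robustness to all intraoperative conditions.

## Benchmark problem sizes

The bundled validation harness uses: 24-frame pure-translation stacks for
tracking accuracy (4 markers); 4 s heartbeat-only sequences for
stabilization residuals; 5 + 5 recordings of 20 stimuli each (200 total)
for the sensitivity/specificity operating point; 4 heartbeat-only
recordings of 20 stimuli for rejection; and 50 eight-level sweeps
(12…40 in steps of 4, 1.2 s spacing) at SNR 8 for eSRT recovery, scored
against the brute-force oracle "lowest tested level whose true amplitude
exceeds k × that sweep's measured floor".

## Statistics layer

Rater comparisons are 2×2 contingency tables (detected/undetected per
rater) tested with Pearson's chi-square (1 df) via
`scipy.stats.chi2_contingency`; the Yates continuity correction is off by
default and available as a flag — the published software-versus-surgeon
p-value reproduces with the uncorrected statistic, while one of the
observer-pair p-values rounds better with Yates, so neither convention is
hard-coded. The six pairwise p-values are Bonferroni-adjusted
(`min(1, 6p)`). Intensity–amplitude association uses Pearson's r with the
two-sided t-test. Per-patient applied/detected counts for the four raters
ship as a CSV so this layer is runnable without any video.

## Numerical notes and limitations

- All randomness flows through explicit integer seeds; identical inputs
  give bit-identical frames, trajectories and reports.
- Frames are 8-bit grayscale end to end; sub-pixel information survives
  quantization because sensor noise acts as dither.
- MSER region identity ties break toward the larger area and lower
  threshold; marker-selection ties break by (y, x) center order, so all
  outputs are order-stable.
- The stabilizer's translation-only model leaves rotation/zoom residuals
  undetected; the forward–backward bound (1 px) is the only guard against
  slow template decorrelation in long recordings.
- Detection operates on a scalar magnitude; the twitch direction is
  estimated nowhere, and motion components along the optical axis are
  invisible by construction.
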