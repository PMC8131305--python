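"""Stimulus-locked reflex decisions from marker trajectories.

The per-frame tendon displacement is the median across valid markers of each
marker's distance from its baseline position.  The trajectory signal is
denoised with a Savitzky–Golay filter — a local least-squares polynomial
smoother that flattens heartbeat-rate oscillation while conserving the brief
displacement peak of a stapedius twitch.  A stimulus counts as a reflex when
the baseline-corrected peak inside the post-onset response window exceeds
``k`` times the background-noise floor, quantified robustly as
``1.4826 × MAD`` of the pre-onset baseline samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import StimulusEvent
from .tracking import TrajectorySet, displacement_magnitudes


class SignalCoverageError(RuntimeError):
    """Too few frames with enough valid markers to form a displacement signal."""


class NoiseEstimationError(RuntimeError):
    """Baseline too short to estimate the noise floor."""


@dataclass(frozen=True)
class DetectorParams:
    """Detection windows, smoothing and threshold.

    ``baseline_window_s`` ends at the stimulus onset; ``response_window_s``
    starts there.  The threshold is ``threshold_k`` noise-floor multiples.
    """

    savgol_window_frames: int = 11
    savgol_polyorder: int = 3
    baseline_window_s: float = 0.5
    response_window_s: float = 0.3
    threshold_k: float = 3.0
    min_markers: int = 2
    max_interp_gap_frames: int = 5

    def __post_init__(self) -> None:
        if self.savgol_window_frames % 2 == 0 or self.savgol_window_frames <= self.savgol_polyorder:
            raise ValueError("Savitzky-Golay window must be odd and exceed the polyorder")
        if self.baseline_window_s <= 0 or self.response_window_s <= 0:
            raise ValueError("windows must be positive")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")


@dataclass
class DisplacementSignal:
    """Per-frame scalar tendon displacement in pixels."""

    values: np.ndarray
    fps: float
    n_markers_used: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_markers_used is None:
            self.n_markers_used = np.full(len(self.values), -1)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


@dataclass(frozen=True)
class ReflexDetection:
    """The detector's verdict for one stimulus."""

    stimulus: StimulusEvent
    detected: bool
    motion_vector_length_px: float
    latency_s: float
    noise_floor_px: float
    threshold_px: float

    def __post_init__(self) -> None:
        if self.detected != (self.motion_vector_length_px > self.threshold_px):
            raise ValueError("detected flag inconsistent with peak vs threshold")


@dataclass(frozen=True)
class SRTEstimate:
    """Reflex threshold (eSRT) and dynamic range for one electrode.

    ``esrt_level`` is None when no stimulus at any level elicited a reflex —
    the absent-reflex outcome.  ``monotone`` is False when some level above
    the eSRT went undetected.
    """

    electrode: str
    esrt_level: float | None
    dynamic_range: tuple[float, float] | None
    monotone: bool


def build_signal(traj: TrajectorySet, params: DetectorParams = DetectorParams()) -> DisplacementSignal:
    """Median-across-markers displacement magnitude, per frame.

    Frames with fewer than ``min_markers`` valid markers are gap-filled by
    linear interpolation, up to ``max_interp_gap_frames`` consecutive frames;
    coverage below 90% raises :class:`SignalCoverageError`.
    """
    mags = displacement_magnitudes(traj)
    n_valid = np.sum(traj.valid, axis=1)
    good = n_valid >= params.min_markers
    if good.mean() < 0.9:
        raise SignalCoverageError(
            f"only {good.mean():.0%} of frames have >= {params.min_markers} valid markers"
        )
    values = np.full(len(mags), np.nan)
    values[good] = np.nanmedian(mags[good], axis=1)
    if not good.all():
        _check_gap_lengths(~good, params.max_interp_gap_frames)
        idx = np.arange(len(values))
        values[~good] = np.interp(idx[~good], idx[good], values[good])
    return DisplacementSignal(values=values, fps=traj.fps, n_markers_used=n_valid)


def _check_gap_lengths(bad: np.ndarray, max_gap: int) -> None:
    run = 0
    for b in bad:
        run = run + 1 if b else 0
        if run > max_gap:
            raise SignalCoverageError(f"gap of >{max_gap} consecutive low-coverage frames")


def savgol_smooth(signal: DisplacementSignal, window_frames: int = 11, polyorder: int = 3) -> DisplacementSignal:
    """Savitzky–Golay smoothing; reproduces polynomials of degree <= polyorder."""
    if window_frames % 2 == 0 or window_frames <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window_frames > len(signal):
        raise ValueError("window longer than signal")
    sm = savgol_filter(signal.values, window_frames, polyorder)
    return DisplacementSignal(values=sm, fps=signal.fps, n_markers_used=signal.n_markers_used)


def smooth_trajectories(
    traj: TrajectorySet, window_frames: int = 11, polyorder: int = 3
) -> TrajectorySet:
    """Savitzky–Golay filter each marker's x(t) and y(t) trace.

    Smoothing the coordinate trajectories *before* forming nonnegative
    displacement magnitudes suppresses tracking noise without the rectified
    noise floor that magnitude signals carry.  Validity flags are preserved.
    """
    if window_frames % 2 == 0 or window_frames <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window_frames > traj.positions.shape[0]:
        raise ValueError("window longer than trajectory")
    smoothed = savgol_filter(traj.positions, window_frames, polyorder, axis=0)
    return TrajectorySet(
        positions=smoothed,
        valid=traj.valid.copy(),
        baseline_positions=traj.baseline_positions.copy(),
        fps=traj.fps,
    )


def detrend_trajectories(
    traj: TrajectorySet,
    window_s: float = 2.0,
    stimuli: list[StimulusEvent] | None = None,
    params: DetectorParams | None = None,
) -> TrajectorySet:
    """Re-anchor each marker to its slowly varying rest position.

    The rest position of each coordinate trace is subtracted so that
    displacement magnitudes, measured from the zero baseline, reflect only
    brief excursions; static template offsets and slow physiological drift
    — which otherwise fold into the nonnegative magnitude and distort
    small-twitch gain — cancel exactly.

    When the stimulus schedule is known, the rest position is estimated
    solely from the pre-onset baseline windows (median per window, linearly
    interpolated in between), so stimulus responses can never leak into
    their own reference.  Without a schedule a rolling median of width
    ``window_s`` is used.
    """
    if stimuli:
        p = params or DetectorParams()
        fps = traj.fps
        centers = []
        anchors = []
        for stim in sorted(stimuli, key=lambda s: s.onset_s):
            i_on = int(round(stim.onset_s * fps))
            i_b0 = int(round((stim.onset_s - p.baseline_window_s) * fps))
            if i_b0 < 0 or i_on + 1 > traj.positions.shape[0]:
                continue
            centers.append(0.5 * (i_b0 + i_on))
            anchors.append(np.median(traj.positions[i_b0 : i_on + 1], axis=0))
        if not centers:
            return detrend_trajectories(traj, window_s)
        centers = np.asarray(centers)
        anchors = np.stack(anchors)  # (n_stim, n_markers, 2)
        frames = np.arange(traj.positions.shape[0], dtype=float)
        rest = np.empty_like(traj.positions)
        for m in range(anchors.shape[1]):
            for ax in range(2):
                rest[:, m, ax] = np.interp(frames, centers, anchors[:, m, ax])
    else:
        from scipy.ndimage import median_filter

        n_frames = traj.positions.shape[0]
        size = int(round(window_s * traj.fps))
        size = max(3, min(size | 1, n_frames | 1))
        rest = median_filter(traj.positions, size=(size, 1, 1), mode="nearest")
    return TrajectorySet(
        positions=traj.positions - rest,
        valid=traj.valid.copy(),
        baseline_positions=np.zeros_like(traj.baseline_positions),
        fps=traj.fps,
    )


def notch_heartbeat(
    traj: TrajectorySet, freq_hz: float, q: float = 5.0
) -> TrajectorySet:
    """Remove a narrowband heartbeat artifact from every coordinate trace.

    A zero-phase IIR notch at the measured heartbeat rate suppresses the
    phase-locked residual that survives stabilization; the twitch is
    broadband, so its peak loses only a few percent.
    """
    from scipy.signal import filtfilt, iirnotch

    if not 0 < freq_hz < traj.fps / 2:
        raise ValueError("notch frequency must lie below the Nyquist rate")
    b, a = iirnotch(freq_hz, q, fs=traj.fps)
    return TrajectorySet(
        positions=filtfilt(b, a, traj.positions, axis=0),
        valid=traj.valid.copy(),
        baseline_positions=traj.baseline_positions.copy(),
        fps=traj.fps,
    )


def noise_floor(values: np.ndarray) -> float:
    """Robust noise scale: 1.4826 × median absolute deviation.

    The median is subtracted first, so a constant offset contributes nothing.
    Requires at least 20 samples.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 20:
        raise NoiseEstimationError(f"need >= 20 baseline samples, got {len(values)}")
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def pooled_noise_floor(
    signal: DisplacementSignal,
    stimuli: list[StimulusEvent],
    params: DetectorParams = DetectorParams(),
) -> float:
    """Noise floor pooled over every stimulus's pre-onset baseline segment.

    Each segment is median-subtracted before pooling, so only fluctuations
    about the local level contribute.  Pooling tames the large sampling
    variance a single 0.5 s window would give the MAD estimate.
    """
    fps = signal.fps
    segments = []
    for stim in stimuli:
        i_on = int(round(stim.onset_s * fps))
        i_b0 = int(round((stim.onset_s - params.baseline_window_s) * fps))
        if i_b0 < 0 or i_on + 1 > len(signal):
            continue
        seg = signal.values[i_b0 : i_on + 1]
        segments.append(seg - np.median(seg))
    if not segments:
        raise NoiseEstimationError("no in-range baseline segments")
    return noise_floor(np.concatenate(segments))


def detect_reflex(
    signal: DisplacementSignal,
    stim: StimulusEvent,
    params: DetectorParams = DetectorParams(),
    noise_floor_px: float | None = None,
) -> ReflexDetection:
    """Decide whether ``stim`` elicited a reflex in the smoothed signal.

    The noise floor comes from the pre-onset baseline window — or, when
    ``noise_floor_px`` is given, from a recording-wide pooled estimate —
    and the decision statistic is the baseline-median-corrected peak in the
    response window.
    """
    fps = signal.fps
    i_on = int(round(stim.onset_s * fps))
    i_b0 = int(round((stim.onset_s - params.baseline_window_s) * fps))
    i_r1 = int(round((stim.onset_s + params.response_window_s) * fps))
    if i_b0 < 0 or i_r1 > len(signal):
        raise ValueError(
            f"baseline/response window of stimulus at {stim.onset_s} s exceeds the recording"
        )
    baseline = signal.values[i_b0 : i_on + 1]
    floor = noise_floor(baseline) if noise_floor_px is None else float(noise_floor_px)
    base_med = float(np.median(baseline))
    response = signal.values[i_on + 1 : i_r1 + 1] - base_med
    peak_idx = int(np.argmax(response))
    peak = float(response[peak_idx])
    peak = max(peak, 0.0)
    threshold = params.threshold_k * floor
    detected = peak > threshold
    latency = (i_on + 1 + peak_idx) / fps - stim.onset_s
    return ReflexDetection(
        stimulus=stim,
        detected=bool(detected),
        motion_vector_length_px=peak,
        latency_s=latency,
        noise_floor_px=floor,
        threshold_px=threshold,
    )


def estimate_esrt(detections: list[ReflexDetection]) -> SRTEstimate:
    """Reflex threshold from one electrode's level series.

    The eSRT is the lowest tested level with a detected reflex; the dynamic
    range runs from there to the highest tested level.  ``monotone`` is False
    when any level above the eSRT went undetected.  With no detections at
    all, the absent-reflex outcome (``esrt_level=None``) is returned.
    """
    if not detections:
        raise ValueError("at least one detection record required")
    electrodes = {d.stimulus.electrode for d in detections}
    if len(electrodes) != 1:
        raise ValueError(f"detections span several electrodes: {sorted(electrodes)}")
    electrode = electrodes.pop()
    levels = np.array([d.stimulus.level for d in detections])
    if len(np.unique(levels)) < 2:
        raise ValueError("need >= 2 distinct tested levels")
    flags = np.array([d.detected for d in detections])
    if not flags.any():
        return SRTEstimate(electrode=electrode, esrt_level=None, dynamic_range=None, monotone=True)
    esrt = float(levels[flags].min())
    above = levels > esrt
    monotone = bool(flags[above].all()) if above.any() else True
    return SRTEstimate(
        electrode=electrode,
        esrt_level=esrt,
        dynamic_range=(esrt, float(levels.max())),
        monotone=monotone,
    )
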