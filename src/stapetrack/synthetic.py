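"""Ground-truthed synthetic middle-ear scenes.

The generator renders what the detector assumes about real recordings: a
textured scene (the surgical field) in which an elliptical tendon region
undergoes brief stimulus-locked twitches whose amplitude grows with
stimulation level above a threshold and saturates, superimposed on global
heartbeat-rate oscillation, slow respiratory drift, per-frame camera jitter,
and sensor noise.  Every run is fully determined by its seed, and the true
per-frame motion is returned alongside the rendered frames so downstream
stages can be scored against ground truth.

Amplitude-versus-level law: ``saturation · logistic(slope · (level − threshold))``
— a threshold with saturation, the minimal shape consistent with a reflex
that becomes visible above some level and stops growing at high levels.
Twitch time course: difference of exponentials ``(1 − e^(−t/τ_rise)) e^(−t/τ_decay)``
normalised to unit peak, delayed by a fixed latency after stimulus onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import FrameSequence, RegionOfInterest, StimulusEvent, SyncTrack

_MARGIN = 16  # px of texture rendered beyond each frame edge


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and texture of the synthetic surgical field.

    ``mm_per_px`` is metadata only; the default assumes the 14 mm visual-field
    width of the recording optics spread over ``frame_width`` pixels.
    """

    frame_width: int = 160
    frame_height: int = 120
    tendon_center: tuple[float, float] = (55.0, 60.0)  # (x, y)
    tendon_axes: tuple[float, float] = (26.0, 13.0)  # (semi-major, semi-minor)
    tendon_orientation_rad: float = 0.3
    reference_patch: RegionOfInterest = field(
        default_factory=lambda: RegionOfInterest(104, 60, 44, 44, label="reference")
    )
    texture_seed: int = 0
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.reference_patch.validate_in((self.frame_height, self.frame_width))
        cx, cy = self.tendon_center
        a = max(self.tendon_axes)
        if not (a <= cx <= self.frame_width - a and a <= cy <= self.frame_height - a):
            raise ValueError("tendon ellipse must lie fully inside the frame")
        if self.mm_per_px is None:
            object.__setattr__(self, "mm_per_px", 14.0 / self.frame_width)
        # bounding-box overlap check keeps signal and reference regions disjoint
        r = self.reference_patch
        if (cx + a > r.x and cx - a < r.x + r.width
                and cy + a > r.y and cy - a < r.y + r.height):
            raise ValueError("tendon ellipse overlaps the reference patch")

    def tendon_roi(self, pad: int = 3) -> RegionOfInterest:
        """Tight rectangle around the (rotated) tendon ellipse plus ``pad`` px.

        Mimics the user drawing the ROI snugly on the tendon, which keeps
        marker detection away from the static surroundings.
        """
        cx, cy = self.tendon_center
        a, b = self.tendon_axes
        th = self.tendon_orientation_rad
        half_w = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
        half_h = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
        x0 = max(0, int(np.floor(cx - half_w - pad)))
        y0 = max(0, int(np.floor(cy - half_h - pad)))
        x1 = min(self.frame_width, int(np.ceil(cx + half_w + pad)))
        y1 = min(self.frame_height, int(np.ceil(cy + half_h + pad)))
        return RegionOfInterest(x0, y0, x1 - x0, y1 - y0, label="tendon")


@dataclass(frozen=True)
class NuisanceMotionModel:
    """Global scene motion the stabiliser must remove.

    Heartbeat and respiration are sinusoidal whole-frame translations along
    fixed oblique directions; jitter is per-frame white translation from
    microscope vibration.  ``sensor_noise_sd`` is additive Gaussian intensity
    noise on the 8-bit scale.
    """

    heartbeat_amp_px: float = 0.8
    heartbeat_freq_hz: float = 1.1
    respiration_amp_px: float = 2.0
    respiration_freq_hz: float = 0.25
    jitter_sd_px: float = 0.1
    sensor_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("heartbeat_amp_px", "respiration_amp_px", "jitter_sd_px", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.heartbeat_freq_hz <= 0 or self.respiration_freq_hz <= 0:
            raise ValueError("frequencies must be positive")

    @classmethod
    def none(cls) -> "NuisanceMotionModel":
        return cls(0.0, 1.1, 0.0, 0.25, 0.0, 0.0)


@dataclass(frozen=True)
class TwitchModel:
    """Stimulus-locked tendon twitch: threshold, saturation and kinetics."""

    threshold_level: float = 20.0
    saturation_amp_px: float = 3.0
    slope: float = 0.5
    latency_s: float = 0.06
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.2
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.saturation_amp_px < 0:
            raise ValueError("saturation amplitude must be non-negative")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time constants must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = np.hypot(*d)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak twitch time course at times ``t`` after stimulus onset."""
        tau = np.asarray(t, dtype=float) - self.latency_s
        w = np.where(
            tau > 0,
            (1.0 - np.exp(-np.clip(tau, 0, None) / self.rise_tau_s))
            * np.exp(-np.clip(tau, 0, None) / self.decay_tau_s),
            0.0,
        )
        t_peak = self.rise_tau_s * np.log1p(self.decay_tau_s / self.rise_tau_s)
        peak = (1.0 - np.exp(-t_peak / self.rise_tau_s)) * np.exp(-t_peak / self.decay_tau_s)
        return w / peak

    @property
    def peak_delay_s(self) -> float:
        """Time from stimulus onset to twitch peak."""
        return self.latency_s + self.rise_tau_s * np.log1p(self.decay_tau_s / self.rise_tau_s)

    @property
    def window_s(self) -> float:
        """Duration after onset in which the twitch is non-negligible."""
        return self.latency_s + self.rise_tau_s + 5.0 * self.decay_tau_s


def amplitude_at_level(model: TwitchModel, level: float) -> float:
    """True twitch amplitude (px) elicited by a stimulus at ``level``.

    ``saturation_amp_px · logistic(slope · (level − threshold_level))`` —
    non-decreasing in level and bounded by the saturation amplitude.
    """
    level = np.asarray(level, dtype=float)
    if np.any(level < 0):
        raise ValueError("stimulation level must be non-negative")
    z = model.slope * (level - model.threshold_level)
    out = model.saturation_amp_px / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


@dataclass
class SyntheticGroundTruth:
    """The generator's hidden state, for scoring the pipeline."""

    stimuli: list[StimulusEvent]
    amplitudes_px: np.ndarray  # true twitch amplitude per stimulus
    peak_times_s: np.ndarray  # absolute time of each twitch peak
    nuisance_trace: np.ndarray  # (n_frames, 2): global (dx, dy)
    tendon_displacement_px: np.ndarray  # (n_frames,): |twitch displacement|

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.amplitudes_px):
            raise ValueError("one amplitude per stimulus required")
        if len(self.nuisance_trace) != len(self.tendon_displacement_px):
            raise ValueError("per-frame traces must share their length")


def make_schedule(
    levels,
    electrode: str = "middle",
    start_s: float = 1.0,
    interval_s: float = 1.2,
    patient_id: str = "synthetic",
) -> list[StimulusEvent]:
    """Evenly spaced stimulus schedule at the given levels."""
    return [
        StimulusEvent(
            onset_s=start_s + k * interval_s,
            electrode=electrode,
            level=float(lv),
            patient_id=patient_id,
            stimulus_id=k,
        )
        for k, lv in enumerate(levels)
    ]


def _band_limited_texture(rng, shape, sigma=2.0, lo=40.0, hi=210.0):
    tex = gaussian_filter(rng.standard_normal(shape), sigma)
    tex -= tex.min()
    tex /= tex.max() or 1.0
    return lo + (hi - lo) * tex


def _tendon_alpha(scene: SceneSpec, shift_xy: tuple[float, float], shape) -> np.ndarray:
    """Soft elliptical tendon mask, evaluated analytically at a shifted center.

    Analytic evaluation gives exact sub-pixel placement without any
    resampling artefact; the 0.5 px edge softness stands in for optical blur.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = scene.tendon_center
    x = xx - cx - shift_xy[0]
    y = yy - cy - shift_xy[1]
    th = scene.tendon_orientation_rad
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    a, b = scene.tendon_axes
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # normalise softness to px at the ellipse edge (minor-axis scale)
    return 1.0 / (1.0 + np.exp((r - 1.0) * b / 0.5))


class _FourierLayer:
    """A padded texture translated by exact Fourier phase shift.

    Band-limited textures can be translated by arbitrary sub-pixel amounts
    without interpolation blur; the margin absorbs the periodic wrap-around
    as long as shifts stay below ``_MARGIN`` pixels.
    """

    def __init__(self, big: np.ndarray):
        self.shape = big.shape
        self._fft = np.fft.rfft2(big)
        fy = np.fft.fftfreq(big.shape[0])[:, None]
        fx = np.fft.rfftfreq(big.shape[1])[None, :]
        self._fy = fy
        self._fx = fx

    def sample(self, dx: float, dy: float, h: int, w: int) -> np.ndarray:
        """Texture translated by (+dx, +dy), cropped to the frame window."""
        phase = np.exp(-2j * np.pi * (self._fy * dy + self._fx * dx))
        shifted = np.fft.irfft2(self._fft * phase, s=self.shape)
        return shifted[_MARGIN : _MARGIN + h, _MARGIN : _MARGIN + w]


def _render_textures(scene: SceneSpec):
    rng = np.random.default_rng(scene.texture_seed)
    big_shape = (scene.frame_height + 2 * _MARGIN, scene.frame_width + 2 * _MARGIN)
    # background and tendon share a similar base intensity range so the
    # tendon rim is a weak step: the trackable features are the interior
    # blobs, not mixed edge bands that straddle moving and static layers
    background = _band_limited_texture(rng, big_shape, sigma=2.0, lo=55.0, hi=165.0)
    tendon = _band_limited_texture(rng, big_shape, sigma=1.5, lo=60.0, hi=150.0)
    # discrete bright/dark blobs give the marker detector stable extremal regions
    cx, cy = scene.tendon_center
    a, b = scene.tendon_axes
    th = scene.tendon_orientation_rad
    yy, xx = np.mgrid[0 : big_shape[0], 0 : big_shape[1]]
    # blob density chosen so a tendon-sized ROI yields roughly the default
    # marker budget of the detection stage
    n_blobs = 14
    for i in range(n_blobs):
        rr = 0.72 * np.sqrt(rng.uniform(0.08, 1.0))
        ang = rng.uniform(0, 2 * np.pi)
        u, v = rr * a * np.cos(ang), rr * b * np.sin(ang)
        bx = cx + u * np.cos(th) - v * np.sin(th) + _MARGIN
        by = cy + u * np.sin(th) + v * np.cos(th) + _MARGIN
        sig = rng.uniform(2.0, 3.2)
        amp = 110.0 if i % 2 == 0 else -90.0
        tendon += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))
    tendon = np.clip(tendon, 0, 255)
    return background, tendon


def _nuisance_trace(nuisance: NuisanceMotionModel, times: np.ndarray, rng) -> np.ndarray:
    hb_dir = np.array([1.0, 0.35]) / np.hypot(1.0, 0.35)
    rs_dir = np.array([0.25, 1.0]) / np.hypot(0.25, 1.0)
    hb = nuisance.heartbeat_amp_px * np.sin(2 * np.pi * nuisance.heartbeat_freq_hz * times)
    rs = nuisance.respiration_amp_px * np.sin(
        2 * np.pi * nuisance.respiration_freq_hz * times + 0.7
    )
    trace = hb[:, None] * hb_dir + rs[:, None] * rs_dir
    trace += nuisance.jitter_sd_px * rng.standard_normal((len(times), 2))
    return trace


def synthesize_sequence(
    scene: SceneSpec,
    schedule: list[StimulusEvent],
    nuisance: NuisanceMotionModel,
    twitch: TwitchModel,
    fps: float = 50.0,
    duration_s: float | None = None,
    seed: int = 0,
    sync_sample_rate: float = 22050.0,
) -> tuple[FrameSequence, SyncTrack, SyntheticGroundTruth]:
    """Render the scene under the schedule; return frames, sync audio, truth.

    The whole frame is translated by the nuisance trace; the tendon texture
    is additionally translated by the summed twitch waveforms.  The sync
    track carries one 10 ms tone burst per stimulus at its onset.  Identical
    arguments and seed give bit-identical outputs.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if duration_s is None:
        last = max((s.onset_s for s in schedule), default=0.0)
        duration_s = last + twitch.window_s + 0.5
    n_frames = max(2, int(round(duration_s * fps)))
    times = np.arange(n_frames) / fps
    for s in schedule:
        if s.onset_s >= duration_s:
            raise ValueError(f"stimulus at {s.onset_s} s falls outside the {duration_s} s sequence")
    onsets = np.array([s.onset_s for s in schedule])
    if len(onsets) > 1 and np.any(np.diff(np.sort(onsets)) < twitch.window_s):
        warnings.warn("twitch windows overlap; amplitudes are summed", stacklevel=2)

    rng = np.random.default_rng(seed)
    background, tendon_tex = _render_textures(scene)
    bg_layer = _FourierLayer(background)
    fg_layer = _FourierLayer(tendon_tex)
    g_trace = _nuisance_trace(nuisance, times, rng)

    amplitudes = np.array([amplitude_at_level(twitch, s.level) for s in schedule])
    twitch_scalar = np.zeros(n_frames)
    for s, amp in zip(schedule, amplitudes):
        twitch_scalar += amp * twitch.waveform(times - s.onset_s)
    direction = np.asarray(twitch.direction)

    h, w = scene.frame_height, scene.frame_width
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for k in range(n_frames):
        gdx, gdy = g_trace[k]
        bg = bg_layer.sample(gdx, gdy, h, w)
        tdx = gdx + twitch_scalar[k] * direction[0]
        tdy = gdy + twitch_scalar[k] * direction[1]
        fg = fg_layer.sample(tdx, tdy, h, w)
        am = _tendon_alpha(scene, (tdx, tdy), (h, w))
        frame = bg * (1 - am) + fg * am
        if nuisance.sensor_noise_sd > 0:
            frame = frame + nuisance.sensor_noise_sd * rng.standard_normal((h, w))
        frames[k] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    sync = _make_sync_track(onsets, duration_s, sync_sample_rate)
    truth = SyntheticGroundTruth(
        stimuli=list(schedule),
        amplitudes_px=amplitudes,
        peak_times_s=onsets + twitch.peak_delay_s,
        nuisance_trace=g_trace,
        tendon_displacement_px=np.abs(twitch_scalar),
    )
    return FrameSequence(frames, fps=fps), sync, truth


def _make_sync_track(onsets: np.ndarray, duration_s: float, sample_rate: float) -> SyncTrack:
    n = int(np.ceil(duration_s * sample_rate))
    samples = np.zeros(n)
    burst_len = int(0.010 * sample_rate)
    t = np.arange(burst_len) / sample_rate
    burst = 0.9 * np.sin(2 * np.pi * 2000.0 * t) * np.hanning(burst_len)
    for onset in onsets:
        i0 = int(round(onset * sample_rate))
        i1 = min(n, i0 + burst_len)
        samples[i0:i1] += burst[: i1 - i0]
    return SyncTrack(samples, sample_rate)
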