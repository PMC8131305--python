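"""Frame, audio, stimulus-log and ROI input/output, plus stimulus alignment.

Frames travel as :class:`FrameSequence` — an ordered stack of equally sized
8-bit grayscale images with a frame rate and per-frame timestamps.  Stimuli
arrive either with explicit onsets (an ``onset_s`` column in the log CSV) or
are located on the video timeline through the mono audio sync track that the
recording setup plays simultaneously with each electrical stimulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, filtfilt

ELECTRODES = ("basal", "middle", "apical")

#: ITU-R BT.601 luma weights, fixed so grayscale conversion is reproducible.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised when an on-disk artefact violates the expected format."""


class AlignmentError(ValueError):
    """Raised when sync onsets and stimulus-log records cannot be paired."""


@dataclass
class FrameSequence:
    """A timestamped stack of equally sized grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width), dtype uint8
    fps : float
        Frame rate in Hz.
    timestamps : ndarray, shape (n_frames,), optional
        Seconds; defaults to ``arange(n) / fps``.
    """

    frames: np.ndarray
    fps: float
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n, h, w) stack")
        if len(self.frames) < 2:
            raise FormatError("a frame sequence needs at least 2 frames")
        if self.fps <= 0:
            raise FormatError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise FormatError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        nominal = np.arange(len(self.frames)) / self.fps + self.timestamps[0]
        if np.max(np.abs(self.timestamps - nominal)) > 1e-3:
            raise FormatError("timestamps inconsistent with fps (>1 ms)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle, 0-based, half-open: ``[x, x+w) × [y, y+h)``."""

    x: int
    y: int
    width: int
    height: int
    label: str = "tendon"

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("ROI must be at least 8x8 px")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.label not in ("tendon", "reference"):
            raise ValueError(f"unknown ROI label {self.label!r}")

    def validate_in(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.x + self.width > w or self.y + self.height > h:
            raise ValueError(
                f"ROI {self} exceeds frame of shape {frame_shape}"
            )

    def extract(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y : self.y + self.height, self.x : self.x + self.width]

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))


@dataclass(frozen=True)
class StimulusEvent:
    """One electrical stimulus placed on the video timeline."""

    onset_s: float
    electrode: str
    level: float
    patient_id: str = ""
    stimulus_id: int = 0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset must be non-negative")
        if self.electrode not in ELECTRODES:
            raise ValueError(f"electrode must be one of {ELECTRODES}")


@dataclass
class SyncTrack:
    """Mono audio waveform carrying one tone burst per stimulus."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("sync track must be mono")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sync track contains non-finite samples")


# ---------------------------------------------------------------------------
# frames


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        gray = img[..., :3].astype(float) @ _LUMA
        return np.round(gray).astype(np.uint8)
    raise FormatError(f"unsupported image shape {img.shape}")


def read_frames(path: str | Path, fps: float = 50.0, downsample_factor: int = 1) -> FrameSequence:
    """Read a numbered image-stack directory into a :class:`FrameSequence`.

    ``path`` must be a directory of PNG/TIFF frames; files are taken in
    lexicographic order.  Color images are converted to BT.601 luma.
    ``downsample_factor`` keeps every k-th frame (fps is divided accordingly).
    """
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"not a frame directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise IOError(f"no PNG/TIFF frames under {path}")
    files = files[::downsample_factor]
    frames = []
    shape = None
    for f in files:
        img = _to_gray(iio.imread(f))
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(f"mixed frame sizes: {shape} vs {img.shape} ({f.name})")
        frames.append(img)
    return FrameSequence(np.stack(frames), fps=fps / downsample_factor)


def write_frames(seq: FrameSequence, path: str | Path) -> list[Path]:
    """Write each frame as an 8-bit PNG (``frame_000000.png``, ...)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(seq.frames):
        p = path / f"frame_{i:06d}.png"
        iio.imwrite(p, frame.astype(np.uint8))
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# audio sync


def read_wav(path: str | Path) -> SyncTrack:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return SyncTrack(np.asarray(data, dtype=float), float(rate))


def write_wav(track: SyncTrack, path: str | Path) -> None:
    peak = np.max(np.abs(track.samples)) or 1.0
    scaled = np.round(track.samples / peak * 32767 * min(peak, 1.0)).astype(np.int16)
    wavfile.write(path, int(track.sample_rate), scaled)


def detect_sync_onsets(
    track: SyncTrack,
    envelope_threshold: float = 0.5,
    min_gap_s: float = 0.2,
) -> np.ndarray:
    """Locate tone-burst onsets as rising edges of the smoothed envelope.

    The track is rectified and low-pass filtered (zero-phase Butterworth,
    200 Hz cutoff); rising crossings of ``envelope_threshold × max(envelope)``
    separated by at least ``min_gap_s`` are reported, sorted ascending.
    A silent track yields an empty array. The threshold being a fraction of
    the maximum makes the result invariant to global gain.
    """
    if not 0 < envelope_threshold < 1:
        raise ValueError("envelope_threshold must lie in (0, 1)")
    env = np.abs(track.samples)
    if env.max() == 0:
        return np.array([])
    cutoff = min(200.0, 0.45 * track.sample_rate / 2)
    b, a = butter(4, cutoff / (track.sample_rate / 2))
    env = filtfilt(b, a, env)
    env = np.clip(env, 0, None)
    thr = envelope_threshold * env.max()
    above = env >= thr
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    onsets = []
    last = -np.inf
    for idx in rising:
        t = idx / track.sample_rate
        if t - last >= min_gap_s:
            onsets.append(t)
            last = t
    return np.array(onsets)


# ---------------------------------------------------------------------------
# stimulus logs


def read_stimulus_log(path: str | Path) -> pd.DataFrame:
    """Read a stimulus log CSV with columns
    ``stimulus_id,patient_id,electrode,level[,onset_s]``."""
    df = pd.read_csv(path)
    required = {"stimulus_id", "patient_id", "electrode", "level"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"stimulus log missing columns: {sorted(missing)}")
    bad = set(df["electrode"]) - set(ELECTRODES)
    if bad:
        raise FormatError(f"unknown electrode labels: {sorted(bad)}")
    return df


def align_stimuli(
    onsets: Sequence[float],
    log: pd.DataFrame,
    offset_s: float = 0.0,
) -> list[StimulusEvent]:
    """Pair the k-th sync onset with the k-th log record, preserving order.

    ``offset_s`` shifts every onset by a constant audio-video latency
    (default 0).  Counts must match exactly.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if len(onsets) != len(log):
        raise AlignmentError(
            f"{len(onsets)} sync onsets but {len(log)} log records"
        )
    events = []
    for onset, (_, row) in zip(onsets, log.iterrows()):
        events.append(
            StimulusEvent(
                onset_s=float(onset) + offset_s,
                electrode=str(row["electrode"]),
                level=float(row["level"]),
                patient_id=str(row["patient_id"]),
                stimulus_id=int(row["stimulus_id"]),
            )
        )
    return events


def events_from_log(log: pd.DataFrame, offset_s: float = 0.0) -> list[StimulusEvent]:
    """Build events straight from an ``onset_s`` column (no audio track)."""
    if "onset_s" not in log.columns:
        raise FormatError("stimulus log has no onset_s column and no sync track was given")
    return align_stimuli(log["onset_s"].to_numpy(), log, offset_s)


# ---------------------------------------------------------------------------
# ROI persistence


def read_rois(path: str | Path) -> dict[str, RegionOfInterest]:
    with open(path) as fh:
        payload = json.load(fh)
    rois = {}
    for label, spec in payload.items():
        rois[label] = RegionOfInterest(
            x=int(spec["x"]), y=int(spec["y"]),
            width=int(spec["width"]), height=int(spec["height"]),
            label=label,
        )
    return rois


def write_rois(rois: dict[str, RegionOfInterest], path: str | Path) -> None:
    payload = {
        label: {"x": r.x, "y": r.y, "width": r.width, "height": r.height}
        for label, r in rois.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
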