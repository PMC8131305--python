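"""End-to-end detection: stabilize → markers → track → smooth → decide.

This is the orchestration layer the CLI and the validation harness call.
It also implements the marker re-detection policy: if more than half of the
markers are invalid at a stimulus onset, markers are re-detected on that
frame and tracking restarts from there with fresh baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import (
    DetectorParams,
    DisplacementSignal,
    ReflexDetection,
    SRTEstimate,
    build_signal,
    detect_reflex,
    detrend_trajectories,
    estimate_esrt,
    notch_heartbeat,
    pooled_noise_floor,
    smooth_trajectories,
)
from .io import FrameSequence, RegionOfInterest, StimulusEvent
from .markers import MarkerSet, MSERParams, detect_regions, select_markers
from .stabilize import ShiftTrace, stabilize_sequence
from .tracking import KLTParams, TrackingFailureError, TrajectorySet, track

log = logging.getLogger("stapetrack")


@dataclass
class PipelineResult:
    """Everything the detection pipeline produced, for reporting and QC."""

    detections: list[ReflexDetection]
    signal: DisplacementSignal
    raw_signal: DisplacementSignal
    trajectories: TrajectorySet
    markers: MarkerSet
    shift_trace: ShiftTrace
    qc: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d in self.detections:
            rows.append(
                {
                    "stimulus_id": d.stimulus.stimulus_id,
                    "patient_id": d.stimulus.patient_id,
                    "electrode": d.stimulus.electrode,
                    "level": d.stimulus.level,
                    "detected": d.detected,
                    "motion_vector_length_px": d.motion_vector_length_px,
                    "latency_s": d.latency_s,
                    "noise_floor_px": d.noise_floor_px,
                }
            )
        return pd.DataFrame(rows)

    def esrt_by_electrode(self) -> dict[str, SRTEstimate]:
        out = {}
        for electrode in sorted({d.stimulus.electrode for d in self.detections}):
            dets = sorted(
                (d for d in self.detections if d.stimulus.electrode == electrode),
                key=lambda d: d.stimulus.level,
            )
            levels = {d.stimulus.level for d in dets}
            if len(levels) >= 2:
                out[electrode] = estimate_esrt(dets)
        return out


def run_detection(
    seq: FrameSequence,
    tendon_roi: RegionOfInterest,
    reference_roi: RegionOfInterest,
    stimuli: list[StimulusEvent],
    detector_params: DetectorParams = DetectorParams(),
    mser_params: MSERParams = MSERParams(),
    klt_params: KLTParams = KLTParams(),
    max_markers: int = 8,
    min_separation_px: float = 6.0,
) -> PipelineResult:
    """Run the full reflex-detection pipeline on one recording."""
    stabilized, trace = stabilize_sequence(seq, reference_roi)
    log.info(
        "stabilize: residual quality median=%.3f max_shift=%.2f px",
        float(np.median(trace.quality)),
        trace.max_shift_px,
    )

    # anchor on a short temporal average: suppresses the sensor-noise bias a
    # single anchor frame would imprint on every baseline position
    n_anchor = min(15, len(stabilized))
    anchor = np.clip(
        np.round(stabilized.frames[:n_anchor].mean(axis=0)), 0, 255
    ).astype(stabilized.frames.dtype)
    regions = detect_regions(anchor, tendon_roi, mser_params)
    markers = select_markers(regions, max_markers=max_markers, min_separation_px=min_separation_px)
    log.info("markers: %d regions -> %d markers", len(regions), len(markers))
    if len(markers) < detector_params.min_markers:
        raise RuntimeError(
            f"only {len(markers)} markers found; need >= {detector_params.min_markers}"
        )

    # markers are tracked on the ORIGINAL frames (initialised by the shift
    # trace) and global motion is cancelled differentially with markers
    # tracked in the reference patch: no resampling enters the trajectories,
    # and any static template bias cancels against the baseline
    offsets = np.stack([trace.dx, trace.dy], axis=1)
    ref_common = _reference_common_motion(
        seq, anchor, reference_roi, offsets, mser_params, klt_params
    )
    traj = _track_with_redetection(
        seq, markers, stimuli, tendon_roi, mser_params, klt_params,
        max_markers, min_separation_px, anchor, offsets, ref_common,
    )
    traj_rest = detrend_trajectories(traj, stimuli=stimuli, params=detector_params)
    hb_freq = _dominant_frequency(offsets, seq.fps)
    if hb_freq is not None:
        log.info("notching heartbeat artifact at %.2f Hz", hb_freq)
        traj_rest = notch_heartbeat(traj_rest, hb_freq)
    raw = build_signal(traj_rest, detector_params)
    traj_sm = smooth_trajectories(
        traj_rest, detector_params.savgol_window_frames, detector_params.savgol_polyorder
    )
    smooth = build_signal(traj_sm, detector_params)
    # "exceeding the background noise": the floor is the RAW trajectory
    # noise, pooled over every baseline segment; the Savitzky-Golay stage
    # conserves reflex peaks, so a true twitch still clears it, while
    # smoothed noise peaks fall far below it
    floor = pooled_noise_floor(raw, stimuli, detector_params) if stimuli else None
    detections = [
        detect_reflex(smooth, s, detector_params, noise_floor_px=floor) for s in stimuli
    ]
    n_det = sum(d.detected for d in detections)
    log.info("detector: %d/%d stimuli detected", n_det, len(detections))
    qc = {
        "n_markers": len(markers),
        "median_stabilization_quality": float(np.median(trace.quality)),
        "max_shift_px": trace.max_shift_px,
        "median_noise_floor_px": float(np.median([d.noise_floor_px for d in detections]))
        if detections
        else float("nan"),
    }
    return PipelineResult(
        detections=detections,
        signal=smooth,
        raw_signal=raw,
        trajectories=traj,
        markers=markers,
        shift_trace=trace,
        qc=qc,
    )


def _dominant_frequency(
    offsets: np.ndarray,
    fps: float,
    band: tuple[float, float] = (0.7, 3.0),
    min_prominence: float = 5.0,
) -> float | None:
    """Heartbeat rate from the global shift trace, or None if no clear peak.

    The spectral peak inside the physiological band must stand at least
    ``min_prominence`` times above the band's median power.
    """
    n = offsets.shape[0]
    if n < 128:
        return None
    x = offsets - offsets.mean(axis=0)
    power = (np.abs(np.fft.rfft(x[:, 0])) ** 2 + np.abs(np.fft.rfft(x[:, 1])) ** 2)
    freqs = np.fft.rfftfreq(n, 1.0 / fps)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return None
    band_power = power[in_band]
    med = np.median(band_power)
    peak = band_power.max()
    if med <= 0 or peak < min_prominence * med:
        return None
    return float(freqs[in_band][np.argmax(band_power)])


def _reference_common_motion(
    seq: FrameSequence,
    anchor: np.ndarray,
    reference_roi: RegionOfInterest,
    offsets: np.ndarray,
    mser_params: MSERParams,
    klt_params: KLTParams,
) -> np.ndarray:
    """Per-frame global motion from markers tracked in the reference patch.

    Falls back to the NCC shift trace for frames (or recordings) where too
    few reference markers track reliably.
    """
    regions = detect_regions(anchor, reference_roi, mser_params)
    ref_markers = select_markers(regions, max_markers=6, min_separation_px=6.0)
    if len(ref_markers) < 2:
        log.info("reference patch yields %d markers; using NCC trace only", len(ref_markers))
        return offsets
    try:
        rtraj = track(seq, ref_markers, klt_params, template_image=anchor, frame_offsets=offsets)
    except TrackingFailureError:
        return offsets
    disp = rtraj.positions - rtraj.baseline_positions[None, :, :]
    w = rtraj.valid[..., None].astype(float)
    n_valid = w.sum(axis=1)
    common = (disp * w).sum(axis=1) / np.maximum(n_valid, 1.0)
    bad = (n_valid[:, 0] < 1)
    common[bad] = offsets[bad]
    return common


def _corrected(traj: TrajectorySet, ref_common: np.ndarray) -> TrajectorySet:
    return TrajectorySet(
        positions=traj.positions - ref_common[:, None, :],
        valid=traj.valid,
        baseline_positions=traj.baseline_positions,
        fps=traj.fps,
    )


def _track_with_redetection(
    seq: FrameSequence,
    markers: MarkerSet,
    stimuli: list[StimulusEvent],
    tendon_roi: RegionOfInterest,
    mser_params: MSERParams,
    klt_params: KLTParams,
    max_markers: int,
    min_separation_px: float,
    anchor: np.ndarray,
    offsets: np.ndarray,
    ref_common: np.ndarray,
) -> TrajectorySet:
    """Track, re-seeding markers when >50% are lost at a stimulus onset.

    Re-seeded segments restart with fresh baseline positions; the stitched
    trajectory keeps per-frame validity of whichever marker set was live.
    """
    onset_frames = sorted(
        {int(round(s.onset_s * seq.fps)) for s in stimuli if s.onset_s < seq.duration_s}
    )
    traj = _corrected(
        track(seq, markers, klt_params, template_image=anchor, frame_offsets=offsets),
        ref_common,
    )
    for f in onset_frames:
        if f >= len(seq) or traj.valid[f].mean() > 0.5:
            continue
        log.warning("re-detecting markers at frame %d (coverage %.0f%%)", f, 100 * traj.valid[f].mean())
        regions = detect_regions(seq.frames[f], tendon_roi, mser_params)
        new_markers = select_markers(regions, max_markers, min_separation_px)
        if len(new_markers) == 0:
            continue
        tail_seq = FrameSequence(seq.frames[f:], fps=seq.fps)
        tail = _corrected(
            track(tail_seq, new_markers, klt_params, frame_offsets=offsets[f:] - offsets[f]),
            ref_common[f:] - ref_common[f],
        )
        n_new = tail.positions.shape[1]
        n_frames = len(seq)
        positions = np.zeros((n_frames, n_new, 2))
        valid = np.zeros((n_frames, n_new), dtype=bool)
        positions[f:] = tail.positions
        valid[f:] = tail.valid
        # keep the old tracks where they were still alive, the new ones after
        traj = TrajectorySet(
            positions=np.concatenate([traj.positions, positions], axis=1),
            valid=np.concatenate([traj.valid, valid], axis=1),
            baseline_positions=np.concatenate(
                [traj.baseline_positions, tail.baseline_positions], axis=0
            ),
            fps=seq.fps,
        )
    return traj
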