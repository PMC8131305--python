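"""Ground-truth benchmark harness for the detection pipeline.

These routines generate synthetic recordings under the package's standard
study conditions, run the full pipeline, and score it against the
generator's hidden state: sub-pixel tracking error, stabilization
residuals, the detector's sensitivity/specificity operating point, and
reflex-threshold (eSRT) recovery against a brute-force forward-model
oracle.

Twitch SNR is defined against the raw per-marker displacement noise
``sigma_t`` — the robust SD of a single marker's frame-to-frame
displacement fluctuation in a stimulus-free recording — because that is
the measurement noise an individual trajectory carries before the
median-across-markers and Savitzky–Golay stages add their gain.
"""

from __future__ import annotations

import numpy as np

from .detector import DetectorParams, pooled_noise_floor
from .markers import MarkerSet
from .pipeline import run_detection
from .stabilize import stabilize_sequence
from .synthetic import (
    NuisanceMotionModel,
    SceneSpec,
    TwitchModel,
    amplitude_at_level,
    make_schedule,
    synthesize_sequence,
)
from .tracking import KLTParams, displacement_magnitudes, track


def measure_tracking_noise(
    scene: SceneSpec | None = None,
    nuisance: NuisanceMotionModel | None = None,
    seed: int = 0,
    n_stimuli: int = 10,
) -> float:
    """Raw per-marker displacement noise ``sigma_t`` (px, robust SD).

    Runs the pipeline on a recording whose stimuli are far below the reflex
    threshold, then takes the median over markers of the MAD-scaled SD of
    each marker's displacement-magnitude trace.
    """
    scene = scene or SceneSpec()
    nuisance = nuisance or NuisanceMotionModel()
    schedule = make_schedule([5.0] * n_stimuli)
    seq, _, _ = synthesize_sequence(
        scene, schedule, nuisance, TwitchModel(saturation_amp_px=0.0), seed=seed
    )
    result = run_detection(seq, scene.tendon_roi(), scene.reference_patch, schedule)
    mags = displacement_magnitudes(result.trajectories)
    per_marker = []
    for m in range(mags.shape[1]):
        v = mags[:, m]
        v = v[np.isfinite(v)]
        per_marker.append(1.4826 * np.median(np.abs(v - np.median(v))))
    return float(np.median(per_marker))


def tracking_rms_error(seed: int = 0, step_px: float = 0.5, n_frames: int = 24) -> float:
    """RMS tracking error on a noise-free pure-translation sequence."""
    from .synthetic import _FourierLayer, _band_limited_texture

    rng = np.random.default_rng(seed)
    shape = (96, 128)
    big = _band_limited_texture(rng, (shape[0] + 32, shape[1] + 32))
    layer = _FourierLayer(big)
    frames = np.stack(
        [
            np.clip(np.round(layer.sample(k * step_px, 0.0, *shape)), 0, 255)
            for k in range(n_frames)
        ]
    ).astype(np.uint8)
    from .io import FrameSequence

    seq = FrameSequence(frames, fps=50.0)
    pts = np.array([[40.0, 40.0], [70.0, 30.0], [55.0, 60.0], [90.0, 55.0]])
    markers = MarkerSet(points=pts, source_regions=list(range(len(pts))), min_separation_px=0.0)
    traj = track(seq, markers, KLTParams())
    truth = step_px * np.arange(n_frames)
    err_x = traj.positions[:, :, 0] - traj.positions[0, :, 0] - truth[:, None]
    err_y = traj.positions[:, :, 1] - traj.positions[0, :, 1]
    return float(np.sqrt(np.mean(err_x**2 + err_y**2)))


def stabilization_metrics(seed: int = 0) -> dict[str, float]:
    """Residual and equivariance of the stabilizer on heartbeat-only input."""
    from .stabilize import estimate_shift

    scene = SceneSpec()
    nuis = NuisanceMotionModel(
        heartbeat_amp_px=0.8, respiration_amp_px=0.0, jitter_sd_px=0.0, sensor_noise_sd=0.0
    )
    seq, _, truth = synthesize_sequence(
        scene, [], nuis, TwitchModel(saturation_amp_px=0.0), duration_s=4.0, seed=seed
    )
    _, trace = stabilize_sequence(seq, scene.reference_patch)
    rel = truth.nuisance_trace - truth.nuisance_trace[0]
    err = np.hypot(trace.dx - rel[:, 0], trace.dy - rel[:, 1])
    residual_rms = float(np.sqrt(np.mean(err**2)))

    # equivariance: rolling a frame by (u, v) must move its estimate by (u, v)
    r = scene.reference_patch
    template = r.extract(seq.frames[0]).astype(float)
    frame = seq.frames[len(seq) // 2].astype(float)
    dx0, dy0, _ = estimate_shift(frame, template, (r.x, r.y))
    u, v = 4, -3
    rolled = np.roll(frame, (v, u), axis=(0, 1))
    dx1, dy1, _ = estimate_shift(rolled, template, (r.x, r.y))
    equivariance = float(max(abs(dx1 - dx0 - u), abs(dy1 - dy0 - v)))
    return {"residual_rms_px": residual_rms, "equivariance_err_px": equivariance}


def operating_point(
    sigma_t: float,
    snr: float = 5.0,
    n_sequences: int = 5,
    stimuli_per_sequence: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity at the given twitch SNR and specificity at amplitude 0.

    ``n_sequences`` recordings of ``stimuli_per_sequence`` stimuli are run
    for each arm (twitch amplitude ``snr * sigma_t`` versus 0).
    """
    scene = SceneSpec()
    nuis = NuisanceMotionModel()
    tp = fp = n_pos = n_neg = 0
    strong = TwitchModel(saturation_amp_px=snr * sigma_t)
    silent = TwitchModel(saturation_amp_px=0.0)
    sched_hi = make_schedule([38.0] * stimuli_per_sequence)
    sched_lo = make_schedule([5.0] * stimuli_per_sequence)
    for k in range(n_sequences):
        seq, _, _ = synthesize_sequence(scene, sched_hi, nuis, strong, seed=seed + 2 * k)
        res = run_detection(seq, scene.tendon_roi(), scene.reference_patch, sched_hi)
        tp += sum(d.detected for d in res.detections)
        n_pos += len(res.detections)
        seq, _, _ = synthesize_sequence(scene, sched_lo, nuis, silent, seed=seed + 2 * k + 1)
        res = run_detection(seq, scene.tendon_roi(), scene.reference_patch, sched_lo)
        fp += sum(d.detected for d in res.detections)
        n_neg += len(res.detections)
    return {
        "sensitivity": tp / n_pos,
        "specificity": 1.0 - fp / n_neg,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "twitch_amplitude_px": snr * sigma_t,
    }


def heartbeat_rejection(n_runs: int = 4, n_stimuli: int = 20, seed: int = 0) -> float:
    """Fraction of heartbeat-only runs with zero detections.

    Pure 1.1 Hz sinusoidal global displacement of 0.8 px, no twitch, with
    ordinary sensor noise; stabilization, the heartbeat notch and the
    smoothing stage should silence the detector.
    """
    scene = SceneSpec()
    nuis = NuisanceMotionModel(
        heartbeat_amp_px=0.8, respiration_amp_px=0.0, jitter_sd_px=0.0, sensor_noise_sd=2.0
    )
    schedule = make_schedule([30.0] * n_stimuli)
    clean = 0
    for k in range(n_runs):
        seq, _, _ = synthesize_sequence(
            scene, schedule, nuis, TwitchModel(saturation_amp_px=0.0), seed=seed + k
        )
        res = run_detection(seq, scene.tendon_roi(), scene.reference_patch, schedule)
        clean += not any(d.detected for d in res.detections)
    return clean / n_runs


def esrt_recovery(
    sigma_t: float,
    n_sweeps: int = 50,
    snr: float = 8.0,
    seed: int = 0,
    params: DetectorParams = DetectorParams(),
) -> dict[str, float]:
    """Fraction of level sweeps whose estimated eSRT lands within one level
    step of the forward-model crossing point.

    The oracle is brute force: the lowest tested level whose true twitch
    amplitude exceeds ``k`` times that sweep's measured noise floor.
    """
    scene = SceneSpec()
    nuis = NuisanceMotionModel()
    levels = np.arange(12.0, 41.0, 4.0)
    step = 4.0
    twitch = TwitchModel(saturation_amp_px=snr * sigma_t, threshold_level=24.0, slope=0.5)
    hits = 0
    errors = []
    for k in range(n_sweeps):
        schedule = make_schedule(levels, interval_s=1.2)
        seq, _, _ = synthesize_sequence(scene, schedule, nuis, twitch, seed=seed + k)
        res = run_detection(
            seq, scene.tendon_roi(), scene.reference_patch, schedule, detector_params=params
        )
        est = res.esrt_by_electrode()["middle"].esrt_level
        floor = pooled_noise_floor(res.raw_signal, schedule, params)
        oracle = next(
            (lv for lv in levels if amplitude_at_level(twitch, lv) > params.threshold_k * floor),
            None,
        )
        if est is not None and oracle is not None:
            errors.append(abs(est - oracle))
            hits += abs(est - oracle) <= step
    return {
        "fraction_within_one_step": hits / n_sweeps,
        "n_sweeps": n_sweeps,
        "mean_abs_error_levels": float(np.mean(errors)) if errors else float("nan"),
    }


def savgol_twitch_attenuation(window: int = 11, polyorder: int = 3, fps: float = 50.0) -> float:
    """Relative loss of a noise-free twitch peak under the default filter."""
    from scipy.signal import savgol_filter

    t = np.arange(0, 2, 1 / fps)
    tw = TwitchModel()
    x = tw.waveform(t - 1.0)
    return float(1.0 - savgol_filter(x, window, polyorder).max() / x.max())
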