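"""Displacement signal, Savitzky–Golay filtering, noise floor, decisions."""

import numpy as np
import pytest

from stapetrack import (
    DetectorParams,
    DisplacementSignal,
    StimulusEvent,
    TrajectorySet,
    TwitchModel,
    build_signal,
    detect_reflex,
    estimate_esrt,
    noise_floor,
    savgol_smooth,
    smooth_trajectories,
)
from stapetrack.detector import NoiseEstimationError, SignalCoverageError

FPS = 50.0


def _traj(mags_xy, valid=None):
    """TrajectorySet from per-frame, per-marker (x, y) offsets."""
    mags_xy = np.asarray(mags_xy, float)
    n_frames, n_markers = mags_xy.shape[:2]
    base = np.stack(
        [np.linspace(10, 50, n_markers), np.full(n_markers, 20.0)], axis=1
    )
    pos = base[None] + mags_xy
    if valid is None:
        valid = np.ones((n_frames, n_markers), bool)
    return TrajectorySet(pos, valid, base.copy(), fps=FPS)


class TestBuildSignal:
    def test_static_markers_zero_signal(self):
        traj = _traj(np.zeros((30, 3, 2)))
        sig = build_signal(traj)
        assert np.all(sig.values == 0)

    def test_median_robust_to_outlier(self):
        offs = np.zeros((30, 3, 2))
        offs[10] = [[1, 0], [2, 0], [9, 0]]
        sig = build_signal(_traj(offs))
        assert sig.values[10] == pytest.approx(2.0)

    def test_low_coverage_interpolated(self):
        offs = np.zeros((40, 2, 2))
        offs[19:22, :, 0] = 4.0
        valid = np.ones((40, 2), bool)
        valid[20, 1] = False  # below min_markers at one frame
        sig = build_signal(_traj(offs, valid), DetectorParams(min_markers=2))
        assert sig.values[20] == pytest.approx(0.5 * (sig.values[19] + sig.values[21]))

    def test_coverage_error(self):
        valid = np.zeros((30, 2), bool)
        valid[:10] = True
        with pytest.raises(SignalCoverageError):
            build_signal(_traj(np.zeros((30, 2, 2)), valid))


class TestSavgolSmooth:
    def test_constant_signal_unchanged(self):
        sig = DisplacementSignal(np.full(50, 2.5), FPS)
        out = savgol_smooth(sig, 11, 3)
        assert np.allclose(out.values, 2.5)

    def test_polynomial_reproduction(self):
        t = np.arange(60) / FPS
        sig = DisplacementSignal(3 * t**2 - t + 0.5, FPS)
        out = savgol_smooth(sig, 11, 3)
        interior = slice(5, -5)
        assert np.allclose(out.values[interior], sig.values[interior], atol=1e-10)

    def test_window_validation(self):
        sig = DisplacementSignal(np.zeros(30), FPS)
        with pytest.raises(ValueError):
            savgol_smooth(sig, 10, 3)
        with pytest.raises(ValueError):
            savgol_smooth(sig, 3, 3)
        with pytest.raises(ValueError):
            savgol_smooth(sig, 51, 3)

    def test_twitch_peak_attenuation_vs_coefficient_oracle(self):
        """Heartbeat sinusoid + twitch at defaults: the twitch peak loses
        < 15%, checked against convolution with independently computed
        least-squares polynomial coefficients."""
        t = np.arange(0, 4, 1 / FPS)
        tw = TwitchModel()
        twitch = 2.0 * tw.waveform(t - 2.0)
        signal = 0.8 * np.sin(2 * np.pi * 1.1 * t) + twitch
        out = savgol_smooth(DisplacementSignal(signal, FPS), 11, 3).values

        # independent coefficients: projection of the unit pulse onto
        # polynomials of degree <= 3 over the 11-point window
        m, order = 11, 3
        x = np.arange(-(m // 2), m // 2 + 1)
        A = np.vander(x, order + 1, increasing=True)
        coeffs = (A @ np.linalg.pinv(A))[m // 2]
        oracle = np.convolve(signal, coeffs[::-1], mode="same")
        assert np.allclose(out[m:-m], oracle[m:-m], atol=1e-10)

        i_peak = np.argmax(twitch)
        window = slice(i_peak - 5, i_peak + 6)
        peak_in = twitch.max()
        peak_out = (out - 0.8 * np.sin(2 * np.pi * 1.1 * t))[window].max()
        assert peak_out > 0.85 * peak_in


class TestSmoothTrajectories:
    def test_preserves_structure_and_reduces_noise(self):
        rng = np.random.default_rng(0)
        offs = rng.normal(0, 0.1, (200, 3, 2))
        traj = _traj(offs)
        sm = smooth_trajectories(traj)
        assert sm.positions.shape == traj.positions.shape
        assert np.array_equal(sm.valid, traj.valid)
        assert sm.positions.std() < traj.positions.std()


class TestNoiseFloor:
    def test_zero_baseline(self):
        assert noise_floor(np.zeros(50)) == 0.0

    def test_constant_offset_removed(self):
        assert noise_floor(np.full(50, 3.3)) == 0.0

    def test_gaussian_sigma_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.2, 500)
        est = noise_floor(x)
        assert est == pytest.approx(x.std(), rel=0.1)

    def test_too_few_samples(self):
        with pytest.raises(NoiseEstimationError):
            noise_floor(np.zeros(10))


def _stim(onset=2.0, level=30.0):
    return StimulusEvent(onset_s=onset, electrode="middle", level=level)


class TestDetectReflex:
    def test_zero_signal_not_detected(self):
        sig = DisplacementSignal(np.zeros(300), FPS)
        det = detect_reflex(sig, _stim())
        assert not det.detected
        assert det.motion_vector_length_px == 0.0

    def test_threshold_consistency_invariant(self):
        rng = np.random.default_rng(1)
        sig = DisplacementSignal(np.abs(rng.normal(0, 0.1, 300)), FPS)
        for onset in (1.0, 2.0, 3.0, 4.0):
            det = detect_reflex(sig, _stim(onset))
            assert det.detected == (det.motion_vector_length_px > det.threshold_px)
            assert det.threshold_px == pytest.approx(
                DetectorParams().threshold_k * det.noise_floor_px
            )

    def test_snr6_twitch_detected_with_correct_latency(self):
        """Signal-level simulation at SNR 6, k = 3: detected, latency within
        40 ms of the true twitch peak time.  The floor is measured on the
        raw signal; the peak on the smoothed one, as in the pipeline."""
        rng = np.random.default_rng(3)
        sigma = 0.1
        t = np.arange(0, 4, 1 / FPS)
        tw = TwitchModel()
        clean = 6 * sigma * tw.waveform(t - 2.0)
        raw = DisplacementSignal(np.abs(clean + rng.normal(0, sigma, len(t))), FPS)
        sig = savgol_smooth(raw, 11, 3)
        floor = noise_floor(raw.values[75:101] - np.median(raw.values[75:101]))
        det = detect_reflex(sig, _stim(2.0), DetectorParams(threshold_k=3.0), noise_floor_px=floor)
        assert det.detected
        assert det.latency_s == pytest.approx(tw.peak_delay_s, abs=0.04)

    def test_subthreshold_specificity(self):
        """Amplitude ~0 in sigma = 0.2 px noise: not detected in >= 95% of
        200 seeded trials (raw-signal floor, smoothed-signal peak)."""
        false_alarms = 0
        params = DetectorParams(threshold_k=3.0)
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            raw = DisplacementSignal(np.abs(rng.normal(0, 0.2, 200)), FPS)
            sig = savgol_smooth(raw, 11, 3)
            base = raw.values[75:101]
            floor = noise_floor(base - np.median(base))
            det = detect_reflex(sig, _stim(2.0), params, noise_floor_px=floor)
            false_alarms += det.detected
        assert false_alarms <= 10

    def test_window_out_of_range(self):
        sig = DisplacementSignal(np.zeros(100), FPS)
        with pytest.raises(ValueError):
            detect_reflex(sig, _stim(0.1))

    def test_monotone_in_amplitude_noise_free(self):
        t = np.arange(0, 4, 1 / FPS)
        tw = TwitchModel()
        peaks = []
        for amp in (0.5, 1.0, 2.0, 3.0):
            sig = DisplacementSignal(np.abs(amp * tw.waveform(t - 2.0)), FPS)
            det = detect_reflex(savgol_smooth(sig, 11, 3), _stim(2.0))
            peaks.append(det.motion_vector_length_px)
        assert np.all(np.diff(peaks) > 0)


class TestEstimateESRT:
    @staticmethod
    def _detections(pairs):
        from stapetrack.detector import ReflexDetection

        out = []
        for level, hit in pairs:
            out.append(
                ReflexDetection(
                    stimulus=_stim(2.0, level),
                    detected=hit,
                    motion_vector_length_px=1.0 if hit else 0.0,
                    latency_s=0.1,
                    noise_floor_px=0.1,
                    threshold_px=0.3,
                )
            )
        return out

    def test_first_detected_level(self):
        est = estimate_esrt(self._detections([(10, False), (15, False), (20, True), (25, True)]))
        assert est.esrt_level == 20
        assert est.monotone
        assert est.dynamic_range == (20, 25)

    def test_non_monotone_flagged(self):
        est = estimate_esrt(self._detections([(10, False), (20, True), (25, False), (30, True)]))
        assert est.esrt_level == 20
        assert not est.monotone

    def test_absent_reflex(self):
        est = estimate_esrt(self._detections([(10, False), (20, False)]))
        assert est.esrt_level is None
        assert est.dynamic_range is None

    def test_requires_input_and_levels(self):
        with pytest.raises(ValueError):
            estimate_esrt([])
        with pytest.raises(ValueError):
            estimate_esrt(self._detections([(10, True), (10, True)]))
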