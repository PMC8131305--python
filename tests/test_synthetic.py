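"""Forward model: amplitude law, rendering fidelity, determinism, sync."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.strategies import floats as st_floats

from stapetrack import (
    NuisanceMotionModel,
    SceneSpec,
    TwitchModel,
    amplitude_at_level,
    detect_sync_onsets,
    make_schedule,
    synthesize_sequence,
)


class TestAmplitudeAtLevel:
    def test_threshold_is_logistic_midpoint(self):
        m = TwitchModel(threshold_level=20, saturation_amp_px=3.0)
        assert amplitude_at_level(m, 20.0) == pytest.approx(1.5)

    def test_saturates_at_high_level(self):
        m = TwitchModel(threshold_level=20, saturation_amp_px=3.0, slope=0.5)
        assert amplitude_at_level(m, 1e6) == pytest.approx(3.0)

    def test_matches_closed_form_logistic(self):
        # independent evaluation of 3.0 / (1 + e^-2) at 4 units above threshold
        m = TwitchModel(threshold_level=20, saturation_amp_px=3.0, slope=0.5)
        expected = 3.0 / (1.0 + np.exp(-2.0))
        assert amplitude_at_level(m, 24.0) == pytest.approx(expected, abs=1e-12)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            amplitude_at_level(TwitchModel(), -1.0)

    @given(
        threshold=st_floats(5.0, 50.0),
        sat=st_floats(0.1, 10.0),
        slope=st_floats(0.05, 3.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_nondecreasing_in_level(self, threshold, sat, slope):
        m = TwitchModel(threshold_level=threshold, saturation_amp_px=sat, slope=slope)
        levels = np.linspace(0, 80, 200)
        amps = amplitude_at_level(m, levels)
        assert np.all(np.diff(amps) >= -1e-12)
        assert np.all(amps <= m.saturation_amp_px + 1e-12)


class TestSceneSpec:
    def test_reference_patch_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SceneSpec(tendon_center=(110.0, 80.0))

    def test_tendon_roi_contains_ellipse(self, scene):
        roi = scene.tendon_roi()
        cx, cy = scene.tendon_center
        assert roi.x <= cx - scene.tendon_axes[1] and cx + scene.tendon_axes[1] <= roi.x + roi.width
        assert roi.y <= cy - scene.tendon_axes[1] and cy + scene.tendon_axes[1] <= roi.y + roi.height


class TestSynthesizeSequence:
    def test_null_motion_gives_constant_frames(self, scene, quiet_nuisance):
        seq, _, _ = synthesize_sequence(
            scene, [], quiet_nuisance, TwitchModel(saturation_amp_px=0.0),
            duration_s=0.5, seed=1,
        )
        assert np.array_equal(seq.frames[0], seq.frames[-1])

    def test_same_seed_bit_identical(self, scene):
        sched = make_schedule([30.0], start_s=0.8)
        args = (scene, sched, NuisanceMotionModel(), TwitchModel())
        a, sa, _ = synthesize_sequence(*args, duration_s=2.0, seed=42)
        b, sb, _ = synthesize_sequence(*args, duration_s=2.0, seed=42)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(sa.samples, sb.samples)

    def test_centroid_shift_matches_prescribed_amplitude(self, twitch_sequence, scene):
        """Noise-free render: the bright tendon features move by the true
        twitch amplitude, measured by an intensity-centroid oracle."""
        (seq, _, truth), schedule = twitch_sequence
        roi = scene.tendon_roi()
        peak_frame = int(round(truth.peak_times_s[0] * seq.fps))
        amp = truth.amplitudes_px[0]

        # oracle: intensity centroid of the brightest tendon blob, measured
        # in a fixed window large enough to contain it before and after
        patch0 = roi.extract(seq.frames[0]).astype(float)
        by, bx = np.unravel_index(np.argmax(patch0), patch0.shape)
        win = (slice(by - 8, by + 9), slice(bx - 10, bx + 11))

        def centroid(frame):
            p = roi.extract(frame).astype(float)[win]
            w = np.clip(p - 0.6 * p.max(), 0, None)
            yy, xx = np.mgrid[0 : p.shape[0], 0 : p.shape[1]]
            return np.array([np.sum(w * xx), np.sum(w * yy)]) / np.sum(w)

        shift = centroid(seq.frames[peak_frame]) - centroid(seq.frames[0])
        expected = amp * np.asarray(TwitchModel().direction)
        assert np.linalg.norm(shift - expected) < 0.2

    def test_one_tone_burst_per_stimulus(self, scene, quiet_nuisance):
        sched = make_schedule([25, 30, 35], start_s=1.0, interval_s=1.2)
        _, sync, _ = synthesize_sequence(
            scene, sched, quiet_nuisance, TwitchModel(), seed=0
        )
        onsets = detect_sync_onsets(sync)
        assert len(onsets) == len(sched)
        assert np.allclose(onsets, [s.onset_s for s in sched], atol=0.005)

    def test_ground_truth_shapes(self, scene):
        sched = make_schedule([10, 30], start_s=0.8, interval_s=1.2)
        seq, _, truth = synthesize_sequence(
            scene, sched, NuisanceMotionModel(), TwitchModel(), seed=9
        )
        assert len(truth.stimuli) == len(truth.amplitudes_px) == 2
        assert len(truth.nuisance_trace) == len(seq)
        assert len(truth.tendon_displacement_px) == len(seq)

    def test_overlapping_twitches_warn_and_sum(self, scene, quiet_nuisance):
        sched = make_schedule([40.0, 40.0], start_s=1.0, interval_s=0.1)
        with pytest.warns(UserWarning, match="overlap"):
            _, _, truth = synthesize_sequence(
                scene, sched, quiet_nuisance, TwitchModel(saturation_amp_px=2.0), seed=0
            )
        # summed waveforms exceed what a single stimulus would reach
        assert truth.tendon_displacement_px.max() > 2.0

    def test_empty_schedule_valid(self, scene, quiet_nuisance):
        seq, sync, truth = synthesize_sequence(
            scene, [], quiet_nuisance, TwitchModel(), duration_s=1.0, seed=0
        )
        assert len(seq) == 50
        assert len(truth.stimuli) == 0
        assert detect_sync_onsets(sync).size == 0

    def test_stimulus_outside_duration_rejected(self, scene, quiet_nuisance):
        sched = make_schedule([30.0], start_s=5.0)
        with pytest.raises(ValueError, match="outside"):
            synthesize_sequence(
                scene, sched, quiet_nuisance, TwitchModel(), duration_s=2.0, seed=0
            )


class TestTwitchWaveform:
    def test_unit_peak_and_causality(self):
        tw = TwitchModel()
        t = np.linspace(0, 1.5, 3001)
        w = tw.waveform(t)
        assert w.max() == pytest.approx(1.0, abs=1e-3)
        assert np.all(w[t <= tw.latency_s] == 0)
        assert abs(t[np.argmax(w)] - tw.peak_delay_s) < 2e-3
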