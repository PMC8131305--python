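import numpy as np
import pytest

from stapetrack import (
    NuisanceMotionModel,
    SceneSpec,
    TwitchModel,
    make_schedule,
    synthesize_sequence,
)


@pytest.fixture(scope="session")
def scene():
    return SceneSpec()


@pytest.fixture(scope="session")
def quiet_nuisance():
    """No motion, no noise: deterministic rendering for oracle tests."""
    return NuisanceMotionModel.none()


@pytest.fixture(scope="session")
def textured_image(scene):
    """A single noise-free rendered frame, useful as a registration target."""
    seq, _, _ = synthesize_sequence(
        scene, [], NuisanceMotionModel.none(), TwitchModel(saturation_amp_px=0.0),
        duration_s=0.1, seed=3,
    )
    return seq.frames[0].astype(float)


@pytest.fixture(scope="session")
def heartbeat_sequence(scene):
    """Heartbeat-only global motion, noise-free, no twitch; with ground truth."""
    nuis = NuisanceMotionModel(
        heartbeat_amp_px=0.8, respiration_amp_px=0.0, jitter_sd_px=0.0, sensor_noise_sd=0.0
    )
    return synthesize_sequence(
        scene, [], nuis, TwitchModel(saturation_amp_px=0.0), duration_s=4.0, seed=11
    )


@pytest.fixture(scope="session")
def twitch_sequence(scene, quiet_nuisance):
    """One saturating 3 px twitch, noise-free; with ground truth."""
    schedule = make_schedule([40.0], start_s=1.0)
    return (
        synthesize_sequence(
            scene, schedule, quiet_nuisance, TwitchModel(saturation_amp_px=3.0),
            seed=5,
        ),
        schedule,
    )
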