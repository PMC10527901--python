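import hypothesis
import numpy as np
import pytest

import dicblend as db

hypothesis.settings.register_profile(
    "dicblend", derandomize=True, max_examples=120, deadline=None
)
hypothesis.settings.load_profile("dicblend")


@pytest.fixture(scope="session")
def presets():
    scenes, conditions = db.default_presets()
    return scenes, conditions


@pytest.fixture(scope="session")
def primary_dataset(presets):
    """Default EVOO-SO series under the primary condition, fixed seed."""
    scenes, conditions = presets
    return db.generate_blend_dataset(scenes["EVOO-SO"], conditions["SG-IA"], seed=7)


@pytest.fixture()
def quiet_condition(presets):
    """Primary condition with all randomness switched off."""
    _, conditions = presets
    return conditions["SG-IA"].replace(lightness_jitter_sd=0.0, pixel_noise_sd=0.0)


@pytest.fixture()
def noiseless_scene(presets):
    """EVOO-SO scene without 8-bit clipping (exactly log-linear data)."""
    scenes, _ = presets
    return scenes["EVOO-SO"].replace(clip_raw=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230915)
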