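import numpy as np
import pytest

from facepulse import SyntheticScene, generate_cg_fixture, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 72 bpm scene: no jitter, no dropout, no drift."""
    return generate_scene(
        SyntheticScene(jitter_sigma_px=0.0, drop_prob=0.0, drift_amp=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_scene():
    """Default study conditions: jitter 3 px, 5% dropout, drift 8."""
    return generate_scene(SyntheticScene(seed=0))


@pytest.fixture(scope="session")
def clean_fixture_72():
    """Pure 1.2 Hz Cg sinusoid, 60 s at 30 fps."""
    return generate_cg_fixture(72.0, fps=30.0, duration_s=60.0, noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
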