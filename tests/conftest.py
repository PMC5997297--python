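import numpy as np
import pytest

from cycletrack import SceneConfig, simulate_scene, simulate_trajectories


@pytest.fixture(scope="session")
def clean_scene():
    """Small noise-free channel scene: easy segmentation, exact expectations."""
    cfg = SceneConfig(n_cells=5, n_frames=30, image_shape=(256, 256),
                      mode="channel", background_amplitude=0.0,
                      shot_noise_scale=0.0, seed=11)
    truth, movie = simulate_scene(cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise channel+chemotaxis scene used across pipeline tests."""
    cfg = SceneConfig(n_cells=10, n_frames=40, image_shape=(256, 256),
                      mode="channel_chemotaxis", seed=7)
    truth, movie = simulate_scene(cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def free_truth():
    """Ground-truth trajectories only (no rendering), free 2D motion."""
    cfg = SceneConfig(n_cells=50, n_frames=120, mode="free2d",
                      chemotaxis_bias=0.0, seed=3)
    return cfg, simulate_trajectories(cfg)


@pytest.fixture(scope="session")
def switch_scene():
    """High-SNR scene where every cell crosses the G1→S/G2 handoff with an
    observed G1 plateau; used for switch-frame recovery checks."""
    cfg = SceneConfig(n_cells=12, n_frames=60, mode="channel",
                      image_shape=(768, 512),
                      background_amplitude=5.0, shot_noise_scale=5.0,
                      cycle_phase_offsets=list(np.linspace(0.34, 0.44, 12)),
                      seed=23)
    truth, movie = simulate_scene(cfg)
    return cfg, truth, movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
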