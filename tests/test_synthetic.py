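"""Synthetic scene generator: trajectories, FUCCI traces, rendering, fibers."""

import numpy as np
import pytest

import cycletrack as ct
from cycletrack.synthetic import (PHASE_NAMES, _channel_centers,
                                  cycle_phase_code, fucci_trace,
                                  simulate_fiber_image, simulate_trajectories)


def _base_config(**kw):
    defaults = dict(n_cells=4, n_frames=50, image_shape=(256, 256), seed=5)
    defaults.update(kw)
    return ct.SceneConfig(**defaults)


class TestTrajectories:
    def test_straight_line_in_noise_free_limit(self):
        cfg = _base_config(n_cells=1, n_frames=20, mode="free2d",
                           image_shape=(1024, 1024),
                           heading_noise_G1=0.0, heading_noise_SG2=0.0,
                           chemotaxis_bias=0.0, step_jitter=0.0,
                           cycle_phase_offsets=[0.0], initial_heading=0.0,
                           speed_G1=0.2, speed_SG2=0.2)
        truth = simulate_trajectories(cfg)
        p = ct.persistence(truth.x_um[0], truth.y_um[0])
        assert p == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(truth.x_um[0]) > 0)
        assert np.allclose(truth.y_um[0], truth.y_um[0, 0])

    def test_zero_speed_freezes_positions(self):
        cfg = _base_config(speed_G1=0.0, speed_SG2=0.0)
        truth = simulate_trajectories(cfg)
        assert np.all(truth.x_um == truth.x_um[:, :1])
        assert np.all(truth.y_um == truth.y_um[:, :1])

    def test_speed_ratio_recovered_from_ground_truth(self):
        """Per-step displacement ratio between phases matches the config."""
        cfg = ct.SceneConfig(n_cells=50, n_frames=120, mode="free2d",
                             speed_G1=0.6, speed_SG2=0.5,
                             chemotaxis_bias=0.0, seed=42)
        truth = simulate_trajectories(cfg)
        steps = np.hypot(np.diff(truth.x_um, axis=1),
                         np.diff(truth.y_um, axis=1))
        mid = cfg.t_G1 + cfg.t_overlap / 2
        g1_like = truth.cycle_tau_h[:, :-1] < mid
        ratio = steps[g1_like].mean() / steps[~g1_like].mean()
        # bootstrap CI over cells
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(200):
            idx = rng.integers(0, cfg.n_cells, cfg.n_cells)
            s, g = steps[idx], g1_like[idx]
            boots.append(s[g].mean() / s[~g].mean())
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 1.2 <= hi
        assert ratio == pytest.approx(1.2, rel=0.05)

    def test_channel_mode_respects_walls(self):
        cfg = _base_config(n_cells=12, n_frames=200, mode="channel")
        truth = simulate_trajectories(cfg)
        dev = np.abs(truth.y_um - truth.channel_center_um[:, None])
        assert np.all(dev <= cfg.channel_width / 2 + 1e-9)

    def test_mean_step_length_matches_speed(self):
        """Over many steps the mean step length is speed × frame interval."""
        cfg = ct.SceneConfig(n_cells=100, n_frames=150, mode="free2d",
                             image_shape=(2048, 2048),
                             speed_G1=0.5, speed_SG2=0.5,
                             chemotaxis_bias=0.0, seed=9)
        truth = simulate_trajectories(cfg)
        # boundary reflections fold a step's chord; keep interior cells only
        h_um, w_um = cfg.field_um
        margin = 2 * 0.5 * cfg.frame_interval
        interior = ((truth.x_um.min(1) > margin) & (truth.y_um.min(1) > margin)
                    & (truth.x_um.max(1) < w_um - margin)
                    & (truth.y_um.max(1) < h_um - margin))
        assert interior.sum() > 50
        steps = np.hypot(np.diff(truth.x_um[interior], axis=1),
                         np.diff(truth.y_um[interior], axis=1)).ravel()
        expected = 0.5 * cfg.frame_interval
        se = steps.std() / np.sqrt(steps.size)
        assert abs(steps.mean() - expected) < 3 * se

    def test_chemotaxis_bias_drives_positive_x_drift(self):
        cfg = _base_config(n_cells=20, mode="channel_chemotaxis",
                           chemotaxis_bias=0.5)
        truth = simulate_trajectories(cfg)
        drift = (truth.x_um[:, -1] - truth.x_um[:, 0]).mean()
        assert drift > 0

    def test_determinism(self):
        cfg = _base_config(mode="channel_chemotaxis")
        t1 = simulate_trajectories(cfg)
        t2 = simulate_trajectories(cfg)
        assert np.array_equal(t1.x_um, t2.x_um)
        assert np.array_equal(t1.red, t2.red)

    def test_invalid_motility_raises(self):
        with pytest.raises(ct.ConfigurationError):
            simulate_trajectories(_base_config(speed_G1=-1.0))
        with pytest.raises(ct.ConfigurationError):
            simulate_trajectories(_base_config(chemotaxis_bias=1.5))
        with pytest.raises(ct.ConfigurationError):
            simulate_trajectories(_base_config(t_G1=float("nan")))

    def test_phase_labels_follow_clock_pattern(self):
        """Phases run G1 → earlyS → SG2 contiguously (cyclic restarts allowed)."""
        cfg = _base_config(n_frames=200)
        truth = simulate_trajectories(cfg)
        allowed = {(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 0)}
        for i in range(cfg.n_cells):
            pairs = set(zip(truth.phase[i, :-1], truth.phase[i, 1:]))
            assert pairs <= allowed


class TestFucciTrace:
    def test_all_g1_is_constant_red(self):
        cfg = _base_config()
        red, green = fucci_trace(np.zeros(20, dtype=int), cfg)
        assert np.all(red == cfg.intensity_peak)
        assert np.all(green == 0)

    def test_overlap_midpoint_is_half_peak(self):
        cfg = _base_config()
        labels = np.array([0] * 5 + [1] * 11 + [2] * 5)
        red, green = fucci_trace(labels, cfg)
        mid = 5 + 5  # centre of the 11-frame earlyS run
        assert red[mid] == pytest.approx(cfg.intensity_peak / 2)
        assert green[mid] == pytest.approx(cfg.intensity_peak / 2)

    def test_two_hour_overlap_gives_twelve_dual_signal_frames(self):
        """2 h handoff at 10 min/frame → exactly 12 frames with both signals."""
        cfg = _base_config(n_cells=1, n_frames=150, cycle_phase_offsets=[0.0])
        truth = simulate_trajectories(cfg)
        both = (truth.red[0] > 0) & (truth.green[0] > 0)
        assert both.sum() == 12

    def test_trace_from_string_labels(self):
        cfg = _base_config()
        red, green = fucci_trace(np.array(["G1", "SG2"]), cfg)
        assert red[0] == cfg.intensity_peak and green[1] == cfg.intensity_peak


class TestRendering:
    def test_zero_cells_zero_noise_black_frames(self):
        cfg = _base_config(n_cells=1, speed_G1=0.0, speed_SG2=0.0,
                           background_amplitude=0.0, shot_noise_scale=0.0,
                           intensity_peak=1000.0)
        truth = simulate_trajectories(cfg)
        truth.red[:] = 0
        truth.green[:] = 0
        movie = ct.render_movie(truth, cfg)
        assert np.all(movie.red == 0) and np.all(movie.green == 0)

    def test_blob_peak_at_centroid(self):
        cfg = _base_config(n_cells=1, speed_G1=0.0, speed_SG2=0.0,
                           background_amplitude=0.0, shot_noise_scale=0.0,
                           cycle_phase_offsets=[0.0])
        truth = simulate_trajectories(cfg)
        movie = ct.render_movie(truth, cfg)
        r, c = np.unravel_index(np.argmax(movie.red[0]), movie.red[0].shape)
        assert abs(r - truth.y_um[0, 0] / cfg.pixel_size) <= 1
        assert abs(c - truth.x_um[0, 0] / cfg.pixel_size) <= 1

    def test_render_determinism(self):
        cfg = _base_config(n_frames=5)
        truth = simulate_trajectories(cfg)
        m1 = ct.render_movie(truth, cfg)
        m2 = ct.render_movie(truth, cfg)
        assert np.array_equal(m1.red, m2.red)
        assert np.array_equal(m1.trans, m2.trans)

    def test_too_small_image_raises(self):
        cfg = _base_config(image_shape=(16, 16), blob_radius=5.0)
        truth = simulate_trajectories(cfg)
        with pytest.raises(ct.ConfigurationError):
            ct.render_movie(truth, cfg)


class TestFiberImages:
    def test_degenerate_gaussian_all_same_angle(self):
        _, angles = simulate_fiber_image(50, "gaussian", (128, 128), seed=1,
                                         mu_deg=90.0, sigma_deg=1e-9)
        assert np.allclose(angles, 90.0)

    def test_uniform_angles_have_near_zero_resultant(self):
        """Doubled uniform axial angles have Rayleigh R near 0."""
        _, angles = simulate_fiber_image(10_000, "uniform", (64, 64), seed=2)
        R, _ = ct.rayleigh_test(angles)
        # R̄ for n uniform samples concentrates near 1/sqrt(n)
        assert R < 3.0 / np.sqrt(10_000)

    def test_fiber_determinism(self):
        img1, a1 = simulate_fiber_image(20, "uniform", (64, 64), seed=3)
        img2, a2 = simulate_fiber_image(20, "uniform", (64, 64), seed=3)
        assert np.array_equal(img1, img2) and np.array_equal(a1, a2)


def test_channel_centers_fit_in_field():
    cfg = _base_config()
    centers = _channel_centers(cfg)
    h_um = cfg.image_shape[0] * cfg.pixel_size
    assert np.all((centers > 0) & (centers < h_um))


def test_cycle_phase_code_boundaries():
    cfg = _base_config()
    codes = cycle_phase_code(np.array([0.0, 9.99, 10.0, 11.99, 12.0, 21.9]), cfg)
    assert list(codes) == [0, 0, 1, 1, 2, 2]
    assert list(PHASE_NAMES[codes]) == ["G1", "G1", "earlyS", "earlyS", "SG2", "SG2"]
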