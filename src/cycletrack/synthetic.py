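"""Ground-truthed synthetic FUCCI imaging experiments.

This module generates everything the analysis pipeline consumes, with known
ground truth: persistent-random-walk trajectories whose motility depends on
cell-cycle phase, FUCCI red/green reporter intensity traces with a ~2 h
red-to-green handoff, rendered multi-channel movies (two fluorescence
channels plus a transmitted-light channel) with low-frequency background and
shot noise, and reflection-style fiber images with uniform or Gaussian angle
distributions.

Coordinate convention: x to the right, y down, origin at the centre of the
top-left pixel, pixel indices 0-based.  Positions are in µm; rendering
converts through ``pixel_size``.

Cell-cycle clock: each cell runs G1 (``t_G1`` h) → early-S handoff
(``t_overlap`` h) → S/G2 (``t_SG2`` h) and then restarts in G1 without
dividing.  Phase labels are encoded 0 = G1, 1 = earlyS, 2 = SG2.  Motility
uses the G1 parameters up to the midpoint of the handoff and the S/G2
parameters after it (the same landmark a red-half-decay classifier sees).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import SceneConfig, write_flat
from .errors import ConfigurationError

PHASE_NAMES = np.array(["G1", "earlyS", "SG2"])


@dataclass
class GroundTruth:
    """Per-cell, per-frame truth for a synthetic scene.

    Arrays are shaped (n_cells, n_frames) except ``times_min`` (n_frames,).
    ``channel_center_um`` is None outside channel modes.
    """

    times_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    phase: np.ndarray           # int8 codes into PHASE_NAMES
    red: np.ndarray
    green: np.ndarray
    cycle_tau_h: np.ndarray     # position in the cell-cycle clock, hours
    channel_center_um: Optional[np.ndarray]
    config: SceneConfig

    @property
    def n_cells(self) -> int:
        return self.x_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x_um.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n, t = self.x_um.shape
        cell = np.repeat(np.arange(n), t)
        frame = np.tile(np.arange(t), n)
        return pd.DataFrame({
            "cell_id": cell,
            "frame": frame,
            "t_min": np.tile(self.times_min, n),
            "x_um": self.x_um.ravel(),
            "y_um": self.y_um.ravel(),
            "phase": PHASE_NAMES[self.phase.ravel()],
            "red": self.red.ravel(),
            "green": self.green.ravel(),
        })

    def switch_frames(self) -> np.ndarray:
        """First frame past the red half-decay landmark per cell (or -1).

        The landmark is the midpoint of the earlyS handoff; it is the frame a
        noiseless 50%-of-max-red classifier should flag as the G1→S/G2 switch.
        """
        cfg = self.config
        mid = cfg.t_G1 + cfg.t_overlap / 2.0
        out = np.full(self.n_cells, -1, dtype=int)
        for i in range(self.n_cells):
            past = np.flatnonzero(
                (self.cycle_tau_h[i] >= mid)
                & (self.cycle_tau_h[i] < cfg.t_G1 + cfg.t_overlap + cfg.t_SG2))
            # require the cell to have been observed before the landmark
            before = np.flatnonzero(self.cycle_tau_h[i] < mid)
            if past.size and before.size and past[0] > 0:
                out[i] = past[0]
        return out


@dataclass
class MovieStack:
    """Time-ordered multi-channel frames plus physical calibration."""

    red: np.ndarray     # (T, H, W) float32
    green: np.ndarray
    trans: np.ndarray
    pixel_size: float   # µm / pixel
    frame_interval: float  # minutes

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.red.shape[1:]


# ---------------------------------------------------------------------------
# cell-cycle clock and FUCCI reporter traces

def cycle_phase_code(tau_h: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Phase code (0/1/2) for clock positions ``tau_h`` (hours into cycle)."""
    tau = np.asarray(tau_h)
    code = np.full(tau.shape, 2, dtype=np.int8)
    code[tau < config.t_G1 + config.t_overlap] = 1
    code[tau < config.t_G1] = 0
    return code


def fucci_intensity(tau_h: np.ndarray, config: SceneConfig):
    """True (red, green) reporter intensities at clock positions ``tau_h``.

    Red sits at ``intensity_peak`` through G1 and decays linearly to zero
    across the earlyS handoff; green rises linearly from zero across the
    handoff and holds at the peak through S/G2.
    """
    tau = np.asarray(tau_h, dtype=float)
    peak = config.intensity_peak
    f = np.clip((tau - config.t_G1) / config.t_overlap, 0.0, 1.0)
    red = peak * (1.0 - f)
    green = peak * f
    return red, green


def fucci_trace(phase_labels, config: SceneConfig):
    """Reporter intensities reconstructed from a phase-label sequence alone.

    Within each contiguous earlyS run of length n the ramp fraction at run
    position i is (i + 0.5)/n, so every handoff frame carries both signals
    and an odd-length run has an exact 50/50 midpoint frame.
    """
    labels = np.asarray(phase_labels)
    if labels.dtype.kind in "US" or labels.dtype == object:
        lut = {name: i for i, name in enumerate(PHASE_NAMES)}
        codes = np.array([lut[str(v)] for v in labels], dtype=np.int8)
    else:
        codes = labels.astype(np.int8)
    peak = config.intensity_peak
    red = np.where(codes == 0, peak, 0.0).astype(float)
    green = np.where(codes == 2, peak, 0.0).astype(float)
    in_overlap = codes == 1
    if in_overlap.any():
        idx = np.flatnonzero(in_overlap)
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            n = len(run)
            frac = (np.arange(n) + 0.5) / n
            red[run] = peak * (1.0 - frac)
            green[run] = peak * frac
    return red, green


# ---------------------------------------------------------------------------
# trajectories

def _channel_centers(config: SceneConfig) -> np.ndarray:
    """y-coordinates (µm) of channel centerlines fitting in the field."""
    h_um = config.image_shape[0] * config.pixel_size
    margin = config.channel_pitch / 2.0
    n = max(1, int((h_um - 2 * margin) // config.channel_pitch) + 1)
    span = (n - 1) * config.channel_pitch
    start = (h_um - span) / 2.0
    return start + np.arange(n) * config.channel_pitch


def simulate_trajectories(config: SceneConfig) -> GroundTruth:
    """Phase-dependent persistent random walk for every cell in the scene.

    Per step the heading gains Gaussian noise (sd = heading_noise of the
    current motility phase) and, in ``channel_chemotaxis`` mode, relaxes
    toward +x with strength ``chemotaxis_bias`` (θ ← θ − b·sin θ).  Step
    length is speed × frame_interval with multiplicative Gaussian jitter
    (sd ``step_jitter``).  Channel modes reflect the walker at the channel
    walls; both modes reflect at the field bounds.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_walk = [np.random.default_rng(s) for s in ss.spawn(2)]

    n, T = config.n_cells, config.n_frames
    h_um, w_um = config.field_um
    dt = config.frame_interval

    if config.cycle_phase_offsets is not None:
        offsets = np.asarray(list(config.cycle_phase_offsets), dtype=float)
    else:
        offsets = rng_init.uniform(0.0, 1.0, size=n)

    cycle = config.cycle_hours
    t_h = np.arange(T) * dt / 60.0
    tau = (offsets[:, None] * cycle + t_h[None, :]) % cycle     # (n, T)
    phase = cycle_phase_code(tau, config)
    # reporter intensities integrate over the frame exposure: evaluate the
    # trace at the frame midpoint so an m-frame handoff shows m dual-signal
    # frames rather than m-1
    tau_mid = (tau + dt / 120.0) % cycle
    red, green = fucci_intensity(tau_mid, config)

    in_channel = config.mode in ("channel", "channel_chemotaxis")
    if in_channel:
        centers = _channel_centers(config)
        chan = np.arange(n) % len(centers)
        center_y = centers[chan]
        y0 = center_y + rng_init.uniform(-0.25, 0.25, n) * config.channel_width
        # cells sharing a channel start in staggered x slots so they do not
        # begin on top of each other (collision exclusion is not modelled)
        occupant = np.arange(n) // len(centers)
        n_slots = int(np.ceil(n / len(centers)))
        slot_w = (0.60 - 0.05) * w_um / n_slots
        x0 = 0.05 * w_um + (occupant + rng_init.uniform(0.1, 0.9, n)) * slot_w
        y_lo = center_y - config.channel_width / 2.0
        y_hi = center_y + config.channel_width / 2.0
    else:
        center_y = None
        x0 = rng_init.uniform(0.1, 0.9, n) * w_um
        y0 = rng_init.uniform(0.1, 0.9, n) * h_um
        y_lo = np.zeros(n)
        y_hi = np.full(n, h_um)

    if config.initial_heading is not None:
        theta = np.full(n, float(config.initial_heading))
        rng_init.uniform(-np.pi, np.pi, n)  # keep stream layout stable
    else:
        theta = rng_init.uniform(-np.pi, np.pi, n)
    x = np.empty((n, T)); y = np.empty((n, T))
    x[:, 0], y[:, 0] = x0, y0

    # motility phase: G1 parameters until the reporter-handoff midpoint
    mid = config.t_G1 + config.t_overlap / 2.0
    g1_like = tau < mid
    speed = np.where(g1_like, config.speed_G1, config.speed_SG2)
    noise_sd = np.where(g1_like, config.heading_noise_G1, config.heading_noise_SG2)

    dtheta = rng_walk.standard_normal((n, T - 1))
    jitter = 1.0 + config.step_jitter * rng_walk.standard_normal((n, T - 1))
    jitter = np.clip(jitter, 0.0, None)

    bias = config.chemotaxis_bias if config.mode == "channel_chemotaxis" else 0.0
    for k in range(T - 1):
        theta = theta + noise_sd[:, k] * dtheta[:, k]
        if bias:
            theta = theta - bias * np.sin(theta)
        step = speed[:, k] * dt * jitter[:, k]
        nx = x[:, k] + step * np.cos(theta)
        ny = y[:, k] + step * np.sin(theta)
        # reflect at x bounds
        over = nx > w_um
        nx[over] = 2 * w_um - nx[over]
        under = nx < 0
        nx[under] = -nx[under]
        flip_x = over | under
        theta = np.where(flip_x, np.pi - theta, theta)
        # reflect at walls / y bounds
        over = ny > y_hi
        ny[over] = 2 * y_hi[over] - ny[over]
        under = ny < y_lo
        ny[under] = 2 * y_lo[under] - ny[under]
        flip_y = over | under
        theta = np.where(flip_y, -theta, theta)
        nx = np.clip(nx, 0, w_um)
        ny = np.clip(ny, y_lo, y_hi)
        x[:, k + 1], y[:, k + 1] = nx, ny

    return GroundTruth(
        times_min=np.arange(T) * dt,
        x_um=x, y_um=y, phase=phase, red=red, green=green,
        cycle_tau_h=tau,
        channel_center_um=center_y if in_channel else None,
        config=config,
    )


# ---------------------------------------------------------------------------
# rendering

def _smooth_background(shape, sigma, rng) -> np.ndarray:
    """Gaussian-filtered white noise (periodic boundaries), zero mean, unit sd."""
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.rfftfreq(shape[1])
    transfer = np.exp(-2.0 * np.pi ** 2 * sigma ** 2
                      * (fy[:, None] ** 2 + fx[None, :] ** 2))
    field = np.fft.irfft2(np.fft.rfft2(noise) * transfer, s=shape)
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def _add_blob(img, r_px, c_px, amp, sigma_px, profile="gauss"):
    """Accumulate one blob into ``img`` using a local patch (4 sigma)."""
    h, w = img.shape
    half = int(np.ceil(4 * sigma_px))
    r0, c0 = int(round(r_px)), int(round(c_px))
    rs, re = max(r0 - half, 0), min(r0 + half + 1, h)
    cs, ce = max(c0 - half, 0), min(c0 + half + 1, w)
    if rs >= re or cs >= ce:
        return
    rr = np.arange(rs, re)[:, None] - r_px
    cc = np.arange(cs, ce)[None, :] - c_px
    r2 = rr ** 2 + cc ** 2
    if profile == "gauss":
        img[rs:re, cs:ce] += amp * np.exp(-r2 / (2 * sigma_px ** 2))
    else:  # transmitted-light body + rim
        r = np.sqrt(r2)
        body = -0.4 * amp * np.exp(-(r / sigma_px) ** 4)
        rim = 0.5 * amp * np.exp(-((r - sigma_px) ** 2) / (2 * 1.0 ** 2))
        img[rs:re, cs:ce] += body + rim


def render_movie(truth: GroundTruth, config: Optional[SceneConfig] = None) -> MovieStack:
    """Render a GroundTruth into red/green/transmitted image stacks.

    Fluorescence: sum of isotropic Gaussian blobs (sd ``blob_radius``) scaled
    by the FUCCI trace, plus a smooth low-frequency background (Gaussian-
    filtered white noise, filter sd 25% of the short image side, scaled to sd
    ``background_amplitude`` and offset by twice that so it stays positive)
    plus zero-mean shot noise.  Transmitted light: uniform mid-gray with a
    darker cell body and thin bright rim per cell; channel modes add dark
    wall lines.  Cells whose centroid leaves the field are clipped at render.
    """
    config = config or truth.config
    h, w = config.image_shape
    sigma_px = config.blob_radius / config.pixel_size
    if min(h, w) < 6 * sigma_px:
        raise ConfigurationError(
            f"image_shape {config.image_shape} too small for blob sd "
            f"{sigma_px:.1f} px")
    ss = np.random.SeedSequence((config.seed, 0xBEEF))
    rng_bg, rng_shot = [np.random.default_rng(s) for s in ss.spawn(2)]

    T = truth.n_frames
    mid_gray = 0.5 * config.intensity_peak
    red = np.zeros((T, h, w), dtype=np.float32)
    green = np.zeros((T, h, w), dtype=np.float32)
    trans = np.full((T, h, w), mid_gray, dtype=np.float32)

    col = truth.x_um / config.pixel_size
    row = truth.y_um / config.pixel_size

    wall_rows = []
    if truth.channel_center_um is not None:
        half_w = config.channel_width / 2.0
        for cy in np.unique(truth.channel_center_um):
            for yw in (cy - half_w, cy + half_w):
                rw = int(round(yw / config.pixel_size))
                if 0 <= rw < h:
                    wall_rows.append(rw)

    bg_sigma = 0.25 * min(h, w)
    for t in range(T):
        fr = np.zeros((h, w)); fg = np.zeros((h, w)); ft = np.zeros((h, w))
        for i in range(truth.n_cells):
            r_px, c_px = row[i, t], col[i, t]
            if not (0 <= r_px < h and 0 <= c_px < w):
                continue  # clipped: centroid outside the field this frame
            if truth.red[i, t] > 0:
                _add_blob(fr, r_px, c_px, truth.red[i, t], sigma_px)
            if truth.green[i, t] > 0:
                _add_blob(fg, r_px, c_px, truth.green[i, t], sigma_px)
            _add_blob(ft, r_px, c_px, config.intensity_peak, sigma_px, profile="trans")
        if config.background_amplitude > 0:
            for img in (fr, fg, ft):
                bg = _smooth_background((h, w), bg_sigma, rng_bg)
                img += np.clip(config.background_amplitude * bg
                               + 2 * config.background_amplitude, 0, None)
        if config.shot_noise_scale > 0:
            fr += config.shot_noise_scale * rng_shot.standard_normal((h, w))
            fg += config.shot_noise_scale * rng_shot.standard_normal((h, w))
            ft += config.shot_noise_scale * rng_shot.standard_normal((h, w))
        for rw in wall_rows:
            ft[max(rw - 1, 0):rw + 1, :] -= 0.3 * config.intensity_peak
        red[t] = np.clip(fr, 0, None)
        green[t] = np.clip(fg, 0, None)
        trans[t] = np.clip(trans[t] + ft, 0, None)

    return MovieStack(red=red, green=green, trans=trans,
                      pixel_size=config.pixel_size,
                      frame_interval=config.frame_interval)


def contact_guidance_egf_config(seed: int = 0) -> SceneConfig:
    """Study conditions for microchannel contact guidance under an EGF
    gradient: 50 cells imaged every 10 min for 120 frames in 10 µm channels
    with chemotactic drift, G1 cells 20% faster than S/G2 (0.6 vs 0.5
    µm/min).  The field holds one cell per channel (24 µm pitch) so tracks
    stay unambiguous, matching the sparse seeding of the microchip.
    """
    return SceneConfig(n_cells=50, n_frames=120, mode="channel_chemotaxis",
                       image_shape=(1856, 512), channel_pitch=24.0,
                       speed_G1=0.6, speed_SG2=0.5, seed=seed)


def simulate_scene(config: SceneConfig):
    """Convenience: trajectories + rendered movie for one config."""
    truth = simulate_trajectories(config)
    movie = render_movie(truth, config)
    return truth, movie


def write_scene(out_dir, truth: GroundTruth, movie: MovieStack) -> None:
    """Write the movie (one multi-page TIFF per channel), truth CSV and config."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stack in (("red", movie.red), ("green", movie.green),
                        ("trans", movie.trans)):
        tifffile.imwrite(out / f"{name}.tif", stack.astype(np.float32))
    truth.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
    write_flat(truth.config, out / "scene_config.txt")


# ---------------------------------------------------------------------------
# fiber images

def simulate_fiber_image(n_fibers: int,
                         angle_distribution="uniform",
                         image_shape: Tuple[int, int] = (512, 512),
                         seed: int = 0,
                         mu_deg: float = 90.0,
                         sigma_deg: float = 10.0,
                         line_width: float = 1.5):
    """Render anti-aliased fiber segments; return (image, true angles in deg).

    ``angle_distribution`` is ``"uniform"`` (angles uniform on [0°, 180°)) or
    ``"gaussian"`` (normal with mean ``mu_deg`` and sd ``sigma_deg``, folded
    modulo 180°).  Angles follow the math convention (x right, y up), so a
    0° fiber is horizontal and a 90° fiber vertical in the rendered image.
    """
    if n_fibers < 1:
        raise ConfigurationError("n_fibers must be >= 1")
    if angle_distribution == "gaussian" and sigma_deg < 0:
        raise ConfigurationError("sigma_deg must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if angle_distribution == "uniform":
        angles = rng.uniform(0.0, 180.0, n_fibers)
    elif angle_distribution == "gaussian":
        angles = np.mod(rng.normal(mu_deg, sigma_deg, n_fibers), 180.0)
    else:
        raise ConfigurationError(
            f"angle_distribution must be 'uniform' or 'gaussian', got {angle_distribution!r}")

    img = np.zeros((h, w), dtype=float)
    side = min(h, w)
    lengths = rng.uniform(0.3, 0.7, n_fibers) * side
    r_c = rng.uniform(0.1, 0.9, n_fibers) * h
    c_c = rng.uniform(0.1, 0.9, n_fibers) * w
    rr_idx = np.arange(h)
    for i in range(n_fibers):
        th = np.deg2rad(angles[i])
        dx, dy_up = np.cos(th), np.sin(th)
        # y down in image rows
        half = lengths[i] / 2.0
        r0, c0 = r_c[i] + half * dy_up, c_c[i] - half * dx
        r1, c1 = r_c[i] - half * dy_up, c_c[i] + half * dx
        _draw_soft_line(img, r0, c0, r1, c1, line_width)
    return img, angles


def _draw_soft_line(img, r0, c0, r1, c1, width):
    """Accumulate a Gaussian-profile line segment (anti-aliased)."""
    h, w = img.shape
    n = int(max(abs(r1 - r0), abs(c1 - c0)) * 2) + 2
    ts = np.linspace(0.0, 1.0, n)
    rs = r0 + ts * (r1 - r0)
    cs = c0 + ts * (c1 - c0)
    half = int(np.ceil(2 * width)) + 1
    for r_px, c_px in zip(rs, cs):
        r0i, c0i = int(round(r_px)), int(round(c_px))
        ra, rb = max(r0i - half, 0), min(r0i + half + 1, h)
        ca, cb = max(c0i - half, 0), min(c0i + half + 1, w)
        if ra >= rb or ca >= cb:
            continue
        rr = np.arange(ra, rb)[:, None] - r_px
        cc = np.arange(ca, cb)[None, :] - c_px
        patch = np.exp(-(rr ** 2 + cc ** 2) / (2 * (width / 2) ** 2))
        np.maximum(img[ra:rb, ca:cb], patch, out=img[ra:rb, ca:cb])
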