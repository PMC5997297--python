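"""Experiment configuration objects and flat key=value config file I/O.

All interface units follow the package convention: lengths in µm, times in
minutes (hours where a field name says so), angles in degrees.  Pixels appear
only inside segmentation/rendering.  Config files are flat ``key=value`` text
so they can be hashed byte-for-byte into a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

from .errors import ConfigurationError

MODES = ("free2d", "channel", "channel_chemotaxis")


@dataclass
class SceneConfig:
    """Full parameterisation of a synthetic FUCCI imaging experiment.

    The defaults emulate the imaging conditions of a widefield 20x time lapse:
    frames every 10 minutes, 0.65 µm/pixel, 512x512 field, 10 µm-wide
    microchannels.  Motility is a phase-dependent persistent random walk;
    ``speed_G1``/``speed_SG2`` are in µm/min and ``heading_noise_*`` is the
    per-step standard deviation of the heading increment in radians.
    """

    n_cells: int = 20
    n_frames: int = 120
    frame_interval: float = 10.0        # minutes
    pixel_size: float = 0.65            # µm / pixel
    image_shape: Tuple[int, int] = (512, 512)   # (rows, cols) pixels
    mode: str = "free2d"
    channel_width: float = 10.0         # µm
    channel_pitch: float = 30.0         # µm between channel centerlines
    taper_entry_x: float = 0.0          # µm; tracking starts past this x
    speed_G1: float = 0.6               # µm/min
    speed_SG2: float = 0.5              # µm/min
    heading_noise_G1: float = 0.3       # rad / step
    heading_noise_SG2: float = 0.5      # rad / step
    chemotaxis_bias: float = 0.3        # dimensionless in [0, 1]
    t_G1: float = 10.0                  # hours
    t_overlap: float = 2.0              # hours (red/green handoff)
    t_SG2: float = 10.0                 # hours
    cycle_phase_offsets: Optional[Sequence[float]] = None  # per-cell in [0,1)
    blob_radius: float = 5.0            # µm (Gaussian sd of rendered blob)
    intensity_peak: float = 1000.0      # arbitrary units
    background_amplitude: float = 50.0  # arbitrary units (sd of background)
    shot_noise_scale: float = 20.0      # arbitrary units (sd of shot noise)
    step_jitter: float = 0.10           # multiplicative step-length sd
    initial_heading: Optional[float] = None  # radians; None → uniform random
    seed: int = 0

    @property
    def cycle_hours(self) -> float:
        return self.t_G1 + self.t_overlap + self.t_SG2

    @property
    def field_um(self) -> Tuple[float, float]:
        """(height, width) of the field of view in µm."""
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)

    def validate(self) -> "SceneConfig":
        pos = {
            "n_cells": self.n_cells, "n_frames": self.n_frames,
            "frame_interval": self.frame_interval, "pixel_size": self.pixel_size,
            "channel_width": self.channel_width, "channel_pitch": self.channel_pitch,
            "t_G1": self.t_G1, "t_overlap": self.t_overlap, "t_SG2": self.t_SG2,
            "blob_radius": self.blob_radius, "intensity_peak": self.intensity_peak,
        }
        for name, v in pos.items():
            if not math.isfinite(float(v)) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("speed_G1", "speed_SG2", "heading_noise_G1",
                     "heading_noise_SG2", "background_amplitude",
                     "shot_noise_scale", "step_jitter"):
            v = getattr(self, name)
            if not math.isfinite(float(v)) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.speed_G1 == 0 and self.speed_SG2 == 0:
            pass  # a frozen population is a valid degenerate scene
        if not 0.0 <= self.chemotaxis_bias <= 1.0:
            raise ConfigurationError(
                f"chemotaxis_bias must lie in [0, 1], got {self.chemotaxis_bias!r}")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.channel_width / self.pixel_size < 4:
            raise ConfigurationError(
                "channel_width/pixel_size must be >= 4 pixels so cells are resolvable "
                f"(got {self.channel_width / self.pixel_size:.2f})")
        if self.cycle_phase_offsets is not None:
            offs = list(self.cycle_phase_offsets)
            if len(offs) != self.n_cells:
                raise ConfigurationError("cycle_phase_offsets must have n_cells entries")
            if any(not (0.0 <= o < 1.0) for o in offs):
                raise ConfigurationError("cycle_phase_offsets must lie in [0, 1)")
        return self


@dataclass
class DiffusionConfig:
    """Chemoattractant diffusion problem on the microchannel rectangle.

    The channel is 850 µm long and 10 µm wide by default; the source edge
    (x = L) is held at ``source_concentration``, the sink edge (x = 0) loses
    mass with flux k·C (Robin condition, ``sink_outflux_coefficient`` in
    µm/s — a mass-transfer velocity), and the long PDMS walls are no-flux.
    ``D`` is given in cm²/s as in the experimental description and converted
    internally to µm²/s.

    Boundary overrides (``source_bc``/``sink_bc``) exist to realise analytic
    limiting cases (closed box, perfect sink) used for verification.
    """

    channel_length: float = 850.0       # µm
    channel_width: float = 10.0         # µm
    D: float = 0.5e-4                   # cm²/s
    source_concentration: float = 1.0   # arbitrary units
    sink_outflux_coefficient: float = 5.0   # µm/s; default D_um/L_res, L_res=1 mm
    initial_concentration: float = 0.0
    grid_spacing: float = 5.0           # µm
    time_step: float = 5.0              # s
    total_time: float = 24.0            # hours
    snapshot_interval: float = 0.5      # hours
    method: str = "implicit"            # "implicit" (backward Euler) or "explicit"
    source_bc: str = "dirichlet"        # "dirichlet" | "neumann" (no-flux)
    sink_bc: str = "robin"              # "robin" | "dirichlet0" | "neumann"

    @property
    def D_um2_s(self) -> float:
        return self.D * 1e8  # cm²/s → µm²/s

    def validate(self) -> "DiffusionConfig":
        for name in ("channel_length", "channel_width", "D", "grid_spacing",
                     "time_step", "total_time", "snapshot_interval"):
            v = getattr(self, name)
            if not math.isfinite(float(v)) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {v!r}")
        if self.sink_outflux_coefficient < 0:
            raise ConfigurationError("sink_outflux_coefficient must be >= 0")
        if self.method not in ("implicit", "explicit"):
            raise ConfigurationError("method must be 'implicit' or 'explicit'")
        if self.method == "explicit":
            r = self.D_um2_s * self.time_step / self.grid_spacing ** 2
            if r > 0.25:
                raise ConfigurationError(
                    "explicit scheme violates its stability bound "
                    f"D*dt/dx^2 = {r:.3g} > 1/4 (2D); reduce time_step below "
                    f"{0.25 * self.grid_spacing ** 2 / self.D_um2_s:.3g} s")
        if self.source_bc not in ("dirichlet", "neumann"):
            raise ConfigurationError("source_bc must be 'dirichlet' or 'neumann'")
        if self.sink_bc not in ("robin", "dirichlet0", "neumann"):
            raise ConfigurationError("sink_bc must be 'robin', 'dirichlet0' or 'neumann'")
        return self


@dataclass
class PipelineConfig:
    """End-to-end analysis run: channel TIFF paths, calibration, stage knobs."""

    red_path: str = ""
    green_path: str = ""
    trans_path: str = ""                # optional; empty → fluorescence-only
    out_dir: str = "."
    pixel_size: float = 0.65            # µm / pixel
    frame_interval: float = 10.0        # minutes
    min_object_size: int = 30           # pixels
    use_phase_channel: bool = True
    window: int = 3                     # tracking association window (frames)
    min_track_length: int = 5           # frames; shorter tracks dropped from stats
    min_phase_steps: int = 6            # steps required per phase for ratios
    taper_entry_x: Optional[float] = None   # µm; None → no channel-entry filter
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("calibration (pixel_size, frame_interval) must be > 0")
        if self.min_object_size < 1 or self.window < 2 or self.min_track_length < 1:
            raise ConfigurationError("stage parameters out of range")
        return self


# ---------------------------------------------------------------------------
# flat key=value serialisation

def _format_value(v) -> str:
    if isinstance(v, (tuple, list)):
        return ",".join(_format_value(x) for x in v)
    if isinstance(v, bool):
        return "true" if v else "false"
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def to_flat(cfg) -> str:
    """Serialise a config dataclass to flat ``key=value`` text (sorted keys)."""
    items = dataclasses.asdict(cfg)
    lines = [f"{k}={_format_value(v)}" for k, v in sorted(items.items())]
    return "\n".join(lines) + "\n"


def _parse_scalar(text: str, typ):
    if typ is bool or text in ("true", "false"):
        return text == "true"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def from_flat(text: str, cls):
    """Parse flat ``key=value`` text into a config dataclass of type ``cls``."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ConfigurationError(f"unknown config key: {key}")
        if val == "":
            kwargs[key] = None
            continue
        if "," in val:
            parts = tuple(_parse_scalar(p, None) for p in val.split(","))
            kwargs[key] = parts
        else:
            kwargs[key] = _parse_scalar(val, None)
    out = cls(**kwargs)
    if isinstance(out.__dict__.get("image_shape"), tuple):
        out.image_shape = tuple(int(v) for v in out.image_shape)
    return out


def write_flat(cfg, path) -> None:
    Path(path).write_text(to_flat(cfg), encoding="utf-8")


def read_flat(path, cls):
    return from_flat(Path(path).read_text(encoding="utf-8"), cls)


def config_hash(cfg) -> str:
    """SHA-256 of the flat serialisation; recorded in run manifests."""
    return hashlib.sha256(to_flat(cfg).encode("utf-8")).hexdigest()
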