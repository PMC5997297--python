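"""Chemoattractant gradient formation in a microchannel.

Solves the 2D unsteady diffusion equation ∂C/∂t = D∇²C on the channel
rectangle (length L along x, width W along y) with a constant-concentration
source edge, a concentration-proportional outflux (Robin) sink edge, and
no-flux PDMS walls, starting from zero concentration.  Default geometry and
diffusivity follow the microchip: L = 850 µm, W = 10 µm,
D = 0.5 × 10⁻⁴ cm²/s (converted internally to 5 × 10³ µm²/s).

Because W ≪ L and the walls are no-flux, the width-averaged profile obeys
the 1D problem; the analytic steady state with a Robin sink at x = 0 and
C = C₀ at x = L is linear with slope s = k C₀ / (D + k L) (k the sink
mass-transfer velocity, µm/s).  ``robin_steady_profile`` exposes that closed
form for verification.

The default time stepper is backward Euler with a pre-factorised sparse
matrix (unconditionally stable; its fixed point is the exact discrete steady
state).  An explicit scheme is available and guards its stability bound
D·Δt/Δx² ≤ 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import DiffusionConfig
from .errors import ConfigurationError, DegenerateProfileError

# geometry convention: x = 0 is the sink (cell reservoir) edge, x = L the
# chemoattractant source edge, matching a gradient that drives +x chemotaxis.


@dataclass
class GradientField:
    """Space-time concentration over the channel grid."""

    times_s: np.ndarray          # (n_snapshots,)
    x_um: np.ndarray             # (nx,)
    y_um: np.ndarray             # (ny,)
    concentration: np.ndarray    # (n_snapshots, ny, nx)
    config: DiffusionConfig

    def width_averaged(self) -> np.ndarray:
        """(n_snapshots, nx) profile averaged across the channel width."""
        return self.concentration.mean(axis=1)

    def profile_at(self, t_hours: float) -> np.ndarray:
        """Width-averaged profile at the stored snapshot nearest ``t_hours``."""
        t_s = t_hours * 3600.0
        if t_s < self.times_s[0] - 1e-9 or t_s > self.times_s[-1] + 1e-9:
            raise ValueError(
                f"t = {t_hours} h outside simulated range "
                f"[{self.times_s[0] / 3600}, {self.times_s[-1] / 3600}] h")
        idx = int(np.argmin(np.abs(self.times_s - t_s)))
        return self.width_averaged()[idx]


def _build_operator(cfg: DiffusionConfig):
    """Sparse Laplacian (µm⁻² scale, multiplied by D) with boundary closures.

    Returns (A, b) such that dC/dt = A·C + b for the interior + boundary
    nodes actually solved (Dirichlet nodes are eliminated into b).
    """
    D = cfg.D_um2_s
    dx = cfg.grid_spacing
    nx = int(round(cfg.channel_length / dx)) + 1
    ny = max(int(round(cfg.channel_width / dx)) + 1, 2)
    n = nx * ny

    def idx(j, i):  # j over y (ny), i over x (nx)
        return j * nx + i

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    c0 = cfg.source_concentration
    k = cfg.sink_outflux_coefficient
    r = D / dx ** 2

    def add(a, bb, v):
        rows.append(a); cols.append(bb); vals.append(v)

    def is_fixed(j, i):
        """Dirichlet nodes are eliminated from the operator."""
        if i == nx - 1 and cfg.source_bc == "dirichlet":
            return True, c0
        if i == 0 and cfg.sink_bc == "dirichlet0":
            return True, 0.0
        return False, 0.0

    # Graph-Laplacian links between grid neighbours: omitting a link at the
    # domain edge IS the no-flux condition, and keeps column sums zero so a
    # closed box conserves the plain grid sum of C exactly.
    for j in range(ny):
        for i in range(nx):
            fixed, _ = is_fixed(j, i)
            if fixed:
                continue
            p = idx(j, i)
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                jj, ii = j + dj, i + di
                if not (0 <= jj < ny and 0 <= ii < nx):
                    continue
                nfixed, nval = is_fixed(jj, ii)
                if nfixed:
                    add(p, p, -r)
                    b[p] += r * nval
                else:
                    add(p, idx(jj, ii), r)
                    add(p, p, -r)
            if i == 0 and cfg.sink_bc == "robin":
                add(p, p, -k / dx)  # outflux k·C through the sink face

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, b, nx, ny


def solve_diffusion(config: DiffusionConfig,
                    initial_field: np.ndarray | None = None) -> GradientField:
    """Integrate the diffusion problem and store snapshots.

    Snapshots are taken every ``snapshot_interval`` hours (plus t = 0 and the
    final time).  ``initial_field`` (ny, nx) overrides the uniform
    ``initial_concentration``.  Raises :class:`ConfigurationError` if an
    explicit scheme is requested with a time step violating its stability
    bound.
    """
    config.validate()
    A, b, nx, ny = _build_operator(config)
    n = nx * ny
    dt = config.time_step
    total_s = config.total_time * 3600.0
    n_steps = int(np.ceil(total_s / dt))

    if initial_field is not None:
        if initial_field.shape != (ny, nx):
            raise ConfigurationError(
                f"initial_field must have shape {(ny, nx)}, got {initial_field.shape}")
        C = initial_field.astype(float).ravel().copy()
    else:
        C = np.full(n, config.initial_concentration, dtype=float)
    # Dirichlet nodes kept at their fixed values for output
    fixed_source = config.source_bc == "dirichlet"
    fixed_sink = config.sink_bc == "dirichlet0"

    def apply_fixed(vec):
        if fixed_source:
            vec.reshape(ny, nx)[:, -1] = config.source_concentration
        if fixed_sink:
            vec.reshape(ny, nx)[:, 0] = 0.0
        return vec

    apply_fixed(C)

    snap_every = max(1, int(round(config.snapshot_interval * 3600.0 / dt)))
    times = [0.0]
    snaps = [C.reshape(ny, nx).copy()]

    if config.method == "implicit":
        M = (sp.identity(n, format="csc") - dt * A.tocsc())
        solver = spla.splu(M)
        for s in range(1, n_steps + 1):
            C = solver.solve(C + dt * b)
            apply_fixed(C)
            if s % snap_every == 0 or s == n_steps:
                times.append(s * dt)
                snaps.append(C.reshape(ny, nx).copy())
    else:
        for s in range(1, n_steps + 1):
            C = C + dt * (A @ C + b)
            apply_fixed(C)
            if s % snap_every == 0 or s == n_steps:
                times.append(s * dt)
                snaps.append(C.reshape(ny, nx).copy())

    return GradientField(
        times_s=np.asarray(times),
        x_um=np.linspace(0.0, config.channel_length, nx),
        y_um=np.linspace(0.0, config.channel_width, ny),
        concentration=np.asarray(snaps),
        config=config,
    )


def robin_steady_profile(config: DiffusionConfig, x_um: np.ndarray) -> np.ndarray:
    """Closed-form 1D steady state with Robin sink at x=0, C=C0 at x=L.

    D C'' = 0 with −D C'(0)·(−1) = k C(0) (outflux at the sink face) gives a
    line C(x) = C(0) + s x with s = k C0 / (D + k L); the k → ∞ limit is the
    Dirichlet-0 line C = C0 · x / L.
    """
    D = config.D_um2_s
    k = config.sink_outflux_coefficient
    L = config.channel_length
    c0 = config.source_concentration
    if np.isinf(k):
        return c0 * np.asarray(x_um) / L
    s = k * c0 / (D + k * L)
    c_sink = c0 - s * L
    return c_sink + s * np.asarray(x_um)


def relative_fluorescence(profile: np.ndarray) -> np.ndarray:
    """Min-max normalise a profile: (I − I_min)/(I_max − I_min).

    Raises :class:`DegenerateProfileError` for a constant profile rather than
    dividing by zero.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 2:
        raise DegenerateProfileError("profile needs >= 2 values")
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise DegenerateProfileError("constant profile cannot be normalised")
    return (p - lo) / (hi - lo)


def gradient_steepness(field: GradientField, t_hours: float) -> float:
    """Mean |∂C/∂x| of the width-averaged profile (central differences)."""
    profile = field.profile_at(t_hours)
    slope = np.gradient(profile, field.x_um)
    return float(np.mean(np.abs(slope)))


def stability_report(field: GradientField, t1_hours: float, t2_hours: float) -> float:
    """Relative change in steepness between two snapshots: |s1 − s2| / s1."""
    s1 = gradient_steepness(field, t1_hours)
    s2 = gradient_steepness(field, t2_hours)
    if s1 == 0:
        raise DegenerateProfileError("zero steepness at reference time")
    return abs(s1 - s2) / s1


def total_mass(field: GradientField) -> np.ndarray:
    """Total concentration (grid sum) per snapshot; conserved in a closed box."""
    return field.concentration.sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# geometry bookkeeping for the microchip

def channel_volume_mm3(width_um: float = 10.0, height_um: float = 20.0,
                       length_um: float = 850.0) -> float:
    """Volume of one microchannel in mm³ (defaults: the 10×20×850 µm channel)."""
    return width_um * height_um * length_um * 1e-9


def reservoir_channel_ratio(reservoir_mm3: float = 200.0,
                            channel_mm3: float | None = None) -> float:
    """Reservoir-to-channel volume ratio; ≈10⁶ for the default microchip."""
    if channel_mm3 is None:
        channel_mm3 = channel_volume_mm3()
    return reservoir_mm3 / channel_mm3
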