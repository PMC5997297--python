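"""Migration metrics and group comparisons from phase-labelled tracks.

Metrics follow the standard definitions for time-lapse tracking data:

* instantaneous velocity — displacement between consecutive observations
  divided by the elapsed time (µm/min); steps spanning an occlusion gap use
  the actual elapsed time.
* persistence — net (start-to-end) displacement divided by total path
  length, in [0, 1]; 1 for a straight path, 0 for a closed loop.  A track
  with zero path length has undefined persistence and is excluded with a
  warning.
* per-cell G1:S/G2 ratios — each metric computed on the contiguous G1 and
  S/G2 segments of a single cell's track (early-S overlap frames excluded),
  reported as G1/SG2; a cell lacking ``min_steps`` steps in either phase
  yields no record.

Group comparisons use the two-sample Student t-test (equal variance, per
convention; Welch available via ``equal_var=False``) with the usual
significance stars and mean ± SEM summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError


def instantaneous_velocity(track_df: pd.DataFrame,
                           pixel_size: Optional[float] = None,
                           frame_interval: float = 10.0) -> np.ndarray:
    """Per-step speeds in µm/min for one track (sorted by frame).

    Uses ``x_um``/``y_um`` columns if present, else converts pixel columns
    through ``pixel_size``.  Returns an empty array for single-detection
    tracks.
    """
    grp = track_df.sort_values("frame")
    if "x_um" in grp:
        x = grp["x_um"].to_numpy(dtype=float)
        y = grp["y_um"].to_numpy(dtype=float)
    else:
        if pixel_size is None:
            raise InsufficientDataError("pixel_size needed without x_um/y_um columns")
        x = grp["x_px"].to_numpy(dtype=float) * pixel_size
        y = grp["y_px"].to_numpy(dtype=float) * pixel_size
    frames = grp["frame"].to_numpy(dtype=float)
    if len(x) < 2:
        return np.empty(0)
    dt = np.diff(frames) * frame_interval
    disp = np.hypot(np.diff(x), np.diff(y))
    return disp / dt


def persistence(x_um: Sequence[float], y_um: Sequence[float]) -> float:
    """Net displacement over path length; NaN (with warning) if no motion."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("persistence needs >= 2 steps (3 positions)")
    path = np.hypot(np.diff(x), np.diff(y)).sum()
    if path == 0:
        warnings.warn("zero path length: persistence undefined")
        return float("nan")
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return net / path


def track_persistence(track_df: pd.DataFrame,
                      pixel_size: Optional[float] = None) -> float:
    grp = track_df.sort_values("frame")
    if "x_um" in grp:
        return persistence(grp["x_um"], grp["y_um"])
    return persistence(grp["x_px"].to_numpy() * pixel_size,
                       grp["y_px"].to_numpy() * pixel_size)


def _phase_runs(frames: np.ndarray, phases: np.ndarray, phase: str,
                bridge_gap: int = 1) -> List[np.ndarray]:
    """Index runs of ``phase``; occlusion gaps ≤ ``bridge_gap`` frames bridged."""
    idx = np.flatnonzero(phases == phase)
    if idx.size == 0:
        return []
    runs: List[List[int]] = [[idx[0]]]
    for i in idx[1:]:
        prev = runs[-1][-1]
        if i == prev + 1 and frames[i] - frames[prev] <= bridge_gap + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return [np.asarray(r) for r in runs]


@dataclass
class RatioRecord:
    """Per-cell G1-over-S/G2 metric ratios."""

    track_id: int
    velocity_ratio: float
    persistence_ratio: float
    n_steps_G1: int
    n_steps_SG2: int


def per_cell_ratios(track_df: pd.DataFrame, frame_interval: float = 10.0,
                    min_steps: int = 6) -> Optional[RatioRecord]:
    """G1:S/G2 velocity and persistence ratios for one phase-labelled track.

    Uses the longest contiguous run of each phase (early-S frames excluded);
    returns None unless both runs hold at least ``min_steps`` steps.
    """
    grp = track_df.sort_values("frame").reset_index(drop=True)
    frames = grp["frame"].to_numpy()
    phases = grp["phase"].to_numpy()
    segments = {}
    for phase in ("G1", "SG2"):
        runs = _phase_runs(frames, phases, phase)
        runs = [r for r in runs if len(r) - 1 >= min_steps]
        if not runs:
            return None
        segments[phase] = max(runs, key=len)
    metrics = {}
    for phase, run in segments.items():
        seg = grp.iloc[run]
        v = instantaneous_velocity(seg, frame_interval=frame_interval)
        metrics[phase] = {
            "v": float(np.mean(v)),
            "p": track_persistence(seg),
            "n": len(run) - 1,
        }
    if metrics["SG2"]["v"] == 0 or metrics["SG2"]["p"] in (0.0,) or \
            np.isnan(metrics["G1"]["p"]) or np.isnan(metrics["SG2"]["p"]):
        return None
    tid = int(grp["track_id"].iloc[0]) if "track_id" in grp else -1
    return RatioRecord(
        track_id=tid,
        velocity_ratio=metrics["G1"]["v"] / metrics["SG2"]["v"],
        persistence_ratio=metrics["G1"]["p"] / metrics["SG2"]["p"],
        n_steps_G1=metrics["G1"]["n"],
        n_steps_SG2=metrics["SG2"]["n"],
    )


def channel_entry_filter(track_df: pd.DataFrame,
                         taper_entry_x_um: float) -> Optional[pd.DataFrame]:
    """Clip a track to start at its first frame with x ≥ the taper entry.

    Mirrors initiating tracking at the channel taper: a track that never
    reaches the taper is dropped (returns None).
    """
    grp = track_df.sort_values("frame").reset_index(drop=True)
    x = grp["x_um"].to_numpy(dtype=float)
    past = np.flatnonzero(x >= taper_entry_x_um)
    if past.size == 0:
        return None
    return grp.iloc[past[0]:].reset_index(drop=True)


def summarize_tracks(tracks_df: pd.DataFrame, frame_interval: float = 10.0,
                     min_steps: int = 2) -> pd.DataFrame:
    """Per-track mean velocity (µm/min), persistence and step count."""
    rows = []
    for tid, grp in tracks_df.groupby("track_id"):
        v = instantaneous_velocity(grp, frame_interval=frame_interval)
        if v.size < min_steps:
            continue
        try:
            p = track_persistence(grp)
        except InsufficientDataError:
            p = float("nan")
        rows.append({"track_id": tid, "mean_velocity_um_min": float(np.mean(v)),
                     "persistence": p, "n_steps": int(v.size)})
    return pd.DataFrame(rows)


def phase_velocity_table(tracks_df: pd.DataFrame,
                         frame_interval: float = 10.0) -> pd.DataFrame:
    """Per-step velocities labelled by the phase at the step's start frame.

    Early-S overlap and unknown frames are excluded, matching the exclusion
    of yellow cells from phase-stratified statistics.
    """
    rows = []
    for tid, grp in tracks_df.groupby("track_id"):
        grp = grp.sort_values("frame")
        v = instantaneous_velocity(grp, frame_interval=frame_interval)
        phases = grp["phase"].to_numpy()[:-1]
        for vel, ph in zip(v, phases):
            if ph in ("G1", "SG2"):
                rows.append({"track_id": tid, "phase": ph,
                             "velocity_um_min": float(vel)})
    return pd.DataFrame(rows, columns=["track_id", "phase", "velocity_um_min"])


def g1_velocity_excess_percent(tracks_df: pd.DataFrame,
                               frame_interval: float = 10.0,
                               n_boot: int = 200, seed: int = 0):
    """Percent excess of pooled G1 over S/G2 step velocity, with bootstrap CI.

    Returns (excess_percent, ci_low, ci_high); the CI resamples whole tracks
    (cells are the independent unit) with ``n_boot`` replicates.
    """
    pv = phase_velocity_table(tracks_df, frame_interval=frame_interval)
    if pv.empty:
        raise InsufficientDataError("no phase-labelled steps")

    def excess(table: pd.DataFrame) -> float:
        g1 = table.loc[table.phase == "G1", "velocity_um_min"]
        sg2 = table.loc[table.phase == "SG2", "velocity_um_min"]
        if len(g1) == 0 or len(sg2) == 0:
            return float("nan")
        return 100.0 * (g1.mean() / sg2.mean() - 1.0)

    point = excess(pv)
    ids = pv.track_id.unique()
    rng = np.random.default_rng(seed)
    groups = dict(tuple(pv.groupby("track_id")))
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(ids, size=len(ids), replace=True)
        sample = pd.concat([groups[i] for i in pick], ignore_index=True)
        boots.append(excess(sample))
    boots = np.asarray([b for b in boots if np.isfinite(b)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(point), float(lo), float(hi)


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    p: float
    stars: str


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(samples_a: Sequence[float], samples_b: Sequence[float],
                   equal_var: bool = True) -> GroupComparison:
    """Two-tailed two-sample t-test with mean ± SEM summaries and stars."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise InsufficientDataError("zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()), sem_a=float(sps.sem(a)), n_a=int(a.size),
        mean_b=float(b.mean()), sem_b=float(sps.sem(b)), n_b=int(b.size),
        t=float(t), p=float(p), stars=significance_stars(float(p)),
    )
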