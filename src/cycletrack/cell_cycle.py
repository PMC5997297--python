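"""FUCCI cell-cycle phase classification of tracked cells.

Two analysis modes exist:

* **Longitudinal** (cells followed through the cycle): each frame is G1 when
  the cell's mean red intensity exceeds 50% of that track's maximum red, and
  S/G2 otherwise.  Frames where the green signal is additionally above 50%
  of the track's maximum green are flagged as the early-S red/green overlap.
  The per-track maxima are retrospective (computed over the whole observed
  track).
* **Snapshot** (population statistics): a detection is G1 if only its red
  intensity clears a threshold, S/G2 if only green does, "yellow" (early-S
  overlap) if both do, and unknown if neither.  Default thresholds are 50%
  of the per-movie 99th-percentile of each channel's detection intensities.

Yellow / early-S entries are excluded from phase-stratified statistics, and
the exclusion count is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

PHASES = ("G1", "SG2", "earlyS_overlap", "unknown", "yellow")


@dataclass
class PhaseTrace:
    """Per-frame phase labels for one track."""

    track_id: int
    frames: np.ndarray
    phase: np.ndarray         # strings from PHASES
    max_red: float
    max_green: float
    switch_frame: Optional[int]   # first S/G2 frame after a G1 run, or None


def classify_longitudinal(track_df: pd.DataFrame,
                          red_fraction: float = 0.5,
                          green_fraction: float = 0.5,
                          red_floor: float = 0.0,
                          green_floor: float = 0.0) -> PhaseTrace:
    """Classify each frame of a track by the 50%-of-max-red rule.

    ``red_floor``/``green_floor`` mark a reporter as unexpressed when the
    track never exceeds them (movie-level snapshot thresholds are a natural
    choice): a track with no real red signal is S/G2 throughout rather than
    flickering on background noise, and vice versa for green.
    """
    grp = track_df.sort_values("frame")
    frames = grp["frame"].to_numpy()
    red = grp["mean_red"].to_numpy(dtype=float)
    green = grp["mean_green"].to_numpy(dtype=float)
    tid = int(grp["track_id"].iloc[0]) if "track_id" in grp else -1
    max_red = float(red.max()) if red.size else 0.0
    max_green = float(green.max()) if green.size else 0.0

    red_expressed = max_red > max(red_floor, 0.0)
    green_expressed = max_green > max(green_floor, 0.0)

    if (red_floor > 0 or green_floor > 0) and not (red_expressed
                                                   and green_expressed):
        # floor-based single-reporter calls take precedence over the
        # 50%-of-max rule, which is meaningless on background noise
        if green_expressed:
            label = "SG2"
        elif red_expressed:
            label = "G1"
        else:
            label = "unknown"
        phase = np.full(frames.shape, label, dtype=object)
        return PhaseTrace(tid, frames, phase, max_red, max_green, None)
    if max_red <= 0:
        warnings.warn(f"track {tid}: all-zero red trace; phases unknown")
        phase = np.full(frames.shape, "unknown", dtype=object)
        return PhaseTrace(tid, frames, phase, max_red, max_green, None)

    g1 = red > red_fraction * max_red
    phase = np.where(g1, "G1", "SG2").astype(object)
    if max_green > 0:
        overlap = g1 & (green > green_fraction * max_green)
        phase[overlap] = "earlyS_overlap"

    switch_frame = None
    seen_g1 = False
    for f, p in zip(frames, phase):
        if p in ("G1", "earlyS_overlap"):
            seen_g1 = True
        elif p == "SG2" and seen_g1:
            switch_frame = int(f)
            break
    return PhaseTrace(tid, frames, phase, max_red, max_green, switch_frame)


def classify_tracks(tracks_df: pd.DataFrame, min_frames: int = 5,
                    use_expression_floors: bool = True) -> pd.DataFrame:
    """Longitudinal classification of every track; adds a ``phase`` column.

    Tracks shorter than ``min_frames`` are labelled unknown.  By default the
    movie-level snapshot thresholds serve as expression floors so that
    single-phase tracks do not flicker on background noise.
    """
    out = tracks_df.copy()
    out["phase"] = "unknown"
    if len(tracks_df) == 0:
        return out
    red_floor = green_floor = 0.0
    if use_expression_floors:
        red_floor, green_floor = snapshot_thresholds(tracks_df)
    for tid, grp in tracks_df.groupby("track_id"):
        if len(grp) < min_frames:
            continue
        trace = classify_longitudinal(grp, red_floor=red_floor,
                                      green_floor=green_floor)
        out.loc[grp.sort_values("frame").index, "phase"] = trace.phase
    return out


def snapshot_thresholds(detections: pd.DataFrame,
                        fraction: float = 0.5,
                        percentile: float = 99.0) -> Tuple[float, float]:
    """Per-movie snapshot thresholds: fraction × channel 99th percentile."""
    red_thr = fraction * np.percentile(detections["mean_red"], percentile)
    green_thr = fraction * np.percentile(detections["mean_green"], percentile)
    return float(red_thr), float(green_thr)


def classify_snapshot(mean_red, mean_green,
                      red_threshold: float, green_threshold: float):
    """Vectorised snapshot classification into G1 / SG2 / yellow / unknown."""
    if red_threshold <= 0 or green_threshold <= 0:
        raise ValueError("snapshot thresholds must be > 0")
    red_on = np.asarray(mean_red) > red_threshold
    green_on = np.asarray(mean_green) > green_threshold
    out = np.full(red_on.shape, "unknown", dtype=object)
    out[red_on & ~green_on] = "G1"
    out[~red_on & green_on] = "SG2"
    out[red_on & green_on] = "yellow"
    if out.ndim == 0:
        return str(out)
    return out


def exclude_yellow(classified: pd.DataFrame,
                   phase_column: str = "phase") -> Tuple[pd.DataFrame, int]:
    """Drop yellow / early-S overlap entries; return (filtered, n_excluded)."""
    bad = classified[phase_column].isin(["yellow", "earlyS_overlap"])
    return classified[~bad].reset_index(drop=True), int(bad.sum())
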