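"""Cost-gated multi-frame association of detections into tracks.

The association cost between two detections combines spatial displacement,
size change and fluorescence-intensity change (the ingredients of
multi-temporal association tracking).  Hard gates make a pair unlinkable
(+∞ cost) when the displacement exceeds twice the larger equivalent radius
or the area changes by more than 90%; the spatial gate is adaptive, relaxing
by a factor of 1.5 until at least five candidate pairs are admitted or the
candidate pool is exhausted.

Association runs over a sliding window of ``window`` frames (default 3): at
each frame, open track heads from the previous ``window − 1`` frames compete
for the new detections through an optimal (min-cost, max-cardinality)
assignment; a link that skips a frame pays a 1.25× penalty per skipped
frame.  Unmatched detections open new tracks; heads unmatched for
``window`` frames close.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import InputError

BIG = 1e12          # placeholder cost for forbidden assignments
GATE_GROWTH = 1.5   # adaptive-gate expansion factor per iteration
MIN_CANDIDATES = 5  # gate relaxes until this many finite-cost candidates


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame (pixel units)."""

    frame: int
    label_id: int
    x: float
    y: float
    area: float
    mean_red: float
    mean_green: float

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


def detections_from_dataframe(df: pd.DataFrame) -> List[Detection]:
    return [Detection(int(r.frame), int(r.label_id), float(r.x_px),
                      float(r.y_px), float(r.area_px), float(r.mean_red),
                      float(r.mean_green))
            for r in df.itertuples(index=False)]


def pair_cost(a: Detection, b: Detection, gate_scale: float = 1.0,
              weights: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Association cost between detections in different frames (b later).

    Gates: +∞ when distance > gate_scale · 2 · max(radius) or when the area
    difference exceeds 90% of the larger area.  Otherwise a weighted sum of
    normalised distance, relative area change and relative intensity change.
    """
    if a.frame == b.frame:
        raise InputError("pair_cost requires detections from different frames")
    dist = math.hypot(a.x - b.x, a.y - b.y)
    max_r = max(a.radius, b.radius)
    max_area = max(a.area, b.area)
    if dist > gate_scale * 2.0 * max_r:
        return math.inf
    if max_area > 0 and abs(a.area - b.area) / max_area > 0.9:
        return math.inf
    w_sp, w_sz, w_int = weights
    spatial = dist / (a.radius + b.radius)
    size = abs(a.area - b.area) / max_area if max_area > 0 else 0.0
    inorm = (max(a.mean_red, b.mean_red) + max(a.mean_green, b.mean_green))
    intensity = ((abs(a.mean_red - b.mean_red)
                  + abs(a.mean_green - b.mean_green)) / inorm) if inorm > 0 else 0.0
    return w_sp * spatial + w_sz * size + w_int * intensity


def adaptive_gate(detection: Detection, pool: Sequence[Detection],
                  weights: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Spatial gate scale for one detection against a candidate pool.

    Starts at 1 and multiplies by ``GATE_GROWTH`` until at least
    ``MIN_CANDIDATES`` pool members have finite cost, or every pool member
    is inside the spatial gate (the size gate does not relax).
    """
    if not pool:
        return 1.0
    scale = 1.0
    while True:
        finite = 0
        spatially_open = 0
        for cand in pool:
            dist = math.hypot(detection.x - cand.x, detection.y - cand.y)
            max_r = max(detection.radius, cand.radius)
            if dist <= scale * 2.0 * max_r:
                spatially_open += 1
                if pair_cost(detection, cand, gate_scale=scale,
                             weights=weights) < math.inf:
                    finite += 1
        if finite >= MIN_CANDIDATES or spatially_open == len(pool):
            return scale
        scale *= GATE_GROWTH


@dataclass
class Track:
    """Time-ordered chain of detections for one cell."""

    track_id: int
    detections: List[Detection] = field(default_factory=list)

    @property
    def birth_frame(self) -> int:
        return self.detections[0].frame

    @property
    def death_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def head(self) -> Detection:
        return self.detections[-1]

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class AssociationResult:
    tracks: List[Track]
    total_cost: float
    n_links: int

    def to_dataframe(self, pixel_size: float = 1.0) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for d in tr.detections:
                rows.append({
                    "track_id": tr.track_id, "frame": d.frame,
                    "label_id": d.label_id,
                    "x_px": d.x, "y_px": d.y,
                    "x_um": d.x * pixel_size, "y_um": d.y * pixel_size,
                    "area_px": d.area,
                    "mean_red": d.mean_red, "mean_green": d.mean_green,
                })
        return (pd.DataFrame(rows)
                .sort_values(["track_id", "frame"])
                .reset_index(drop=True))


def associate(detections: Sequence[Detection], window: int = 3,
              gap_penalty: float = 1.25,
              weights: Sequence[float] = (1.0, 1.0, 1.0),
              allow_gaps: bool = True) -> AssociationResult:
    """Link detections into tracks via per-frame optimal assignment.

    Detections are grouped by frame; at each frame the open heads (last seen
    within ``window − 1`` frames) are assigned to the frame's detections by
    minimum total cost at maximum cardinality.  Ties are resolved
    deterministically by sorting detections by (frame, label_id).
    """
    if not detections:
        return AssociationResult([], 0.0, 0)
    by_frame: Dict[int, List[Detection]] = {}
    for d in sorted(detections, key=lambda d: (d.frame, d.label_id)):
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)

    tracks: List[Track] = []
    open_tracks: List[Track] = []
    next_id = 0
    total_cost = 0.0
    n_links = 0

    for f_idx, frame in enumerate(frames):
        dets = by_frame[frame]
        max_gap = (window - 1) if allow_gaps else 1
        heads = [tr for tr in open_tracks
                 if 1 <= frame - tr.head.frame <= max_gap]
        if heads and dets:
            cost = np.full((len(heads), len(dets)), BIG)
            for i, tr in enumerate(heads):
                gate = adaptive_gate(tr.head, dets, weights=weights)
                gap = frame - tr.head.frame - 1
                mult = gap_penalty ** gap
                for j, det in enumerate(dets):
                    c = pair_cost(tr.head, det, gate_scale=gate, weights=weights)
                    if math.isfinite(c):
                        cost[i, j] = c * mult
            n = max(len(heads), len(dets))
            padded = np.full((n, n), BIG)
            padded[:len(heads), :len(dets)] = cost
            rows, cols = linear_sum_assignment(padded)
            matched_dets = set()
            for i, j in zip(rows, cols):
                if i < len(heads) and j < len(dets) and padded[i, j] < BIG / 2:
                    heads[i].detections.append(dets[j])
                    matched_dets.add(j)
                    total_cost += padded[i, j]
                    n_links += 1
            unmatched = [d for j, d in enumerate(dets) if j not in matched_dets]
        else:
            unmatched = list(dets)
        for d in unmatched:
            tr = Track(next_id, [d])
            next_id += 1
            tracks.append(tr)
            open_tracks.append(tr)
        open_tracks = [tr for tr in open_tracks
                       if frame - tr.head.frame < window]

    tracks.sort(key=lambda tr: tr.track_id)
    return AssociationResult(tracks, total_cost, n_links)


def associate_dataframe(df: pd.DataFrame, pixel_size: float = 1.0,
                        window: int = 3, min_track_length: int = 1,
                        **kwargs) -> pd.DataFrame:
    """Associate a detections table; returns a tracks table in px and µm."""
    result = associate(detections_from_dataframe(df), window=window, **kwargs)
    out = result.to_dataframe(pixel_size=pixel_size)
    if min_track_length > 1 and not out.empty:
        sizes = out.groupby("track_id")["frame"].transform("size")
        out = out[sizes >= min_track_length].reset_index(drop=True)
    return out


def link_quality(tracks_df: pd.DataFrame, truth) -> pd.DataFrame:
    """Identity-switch count and purity per track against ground truth.

    Each detection is attributed to the nearest ground-truth cell at its
    frame; purity is the majority fraction, switches count frame-to-frame
    links whose attribution changes.
    """
    px = truth.config.pixel_size
    rows = []
    for tid, grp in tracks_df.groupby("track_id"):
        grp = grp.sort_values("frame")
        ids = []
        for r in grp.itertuples(index=False):
            t = int(r.frame)
            dx = truth.x_um[:, t] - r.x_px * px
            dy = truth.y_um[:, t] - r.y_px * px
            ids.append(int(np.argmin(np.hypot(dx, dy))))
        ids = np.asarray(ids)
        counts = np.bincount(ids)
        purity = counts.max() / len(ids)
        switches = int(np.sum(ids[1:] != ids[:-1]))
        rows.append({"track_id": tid, "n": len(ids),
                     "majority_cell": int(np.argmax(counts)),
                     "purity": purity, "switches": switches})
    return pd.DataFrame(rows)
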