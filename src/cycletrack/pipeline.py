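"""End-to-end pipeline: segment → track → classify → migration statistics.

``analyze_movie`` runs the stages on an in-memory :class:`MovieStack` and
returns the result bundle (detections, tracks, phase-labelled tracks,
per-track metrics, per-cell ratios).  ``run_pipeline`` is the file-based
wrapper driven by a :class:`PipelineConfig`: it reads the channel TIFFs,
writes every artifact under the output directory and records a manifest
with the config hash and package version, so an identical config and inputs
regenerate identical CSV outputs.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cell_cycle import classify_tracks, exclude_yellow
from .config import PipelineConfig, config_hash, to_flat
from .errors import InputError
from .io import read_stack, write_labels, write_manifest, write_table
from .migration import (channel_entry_filter, per_cell_ratios,
                        phase_velocity_table, summarize_tracks)
from .segmentation import segment_movie
from .synthetic import MovieStack
from .tracking import associate_dataframe

log = logging.getLogger("cycletrack")


@dataclass
class PipelineResult:
    detections: pd.DataFrame
    tracks: pd.DataFrame            # phase-labelled
    track_metrics: pd.DataFrame
    ratios: pd.DataFrame
    masks: np.ndarray
    n_excluded_overlap: int


def analyze_movie(movie: MovieStack, config: Optional[PipelineConfig] = None
                  ) -> PipelineResult:
    """Run segmentation, tracking, phase classification and migration stats."""
    cfg = (config or PipelineConfig()).validate()
    t0 = time.perf_counter()
    masks, detections = segment_movie(
        movie, use_phase_channel=cfg.use_phase_channel and movie.trans is not None,
        min_size=cfg.min_object_size)
    log.info("segmentation: %d detections in %.1fs",
             len(detections), time.perf_counter() - t0)

    t0 = time.perf_counter()
    tracks = associate_dataframe(detections, pixel_size=movie.pixel_size,
                                 window=cfg.window,
                                 min_track_length=cfg.min_track_length)
    log.info("tracking: %d tracks in %.1fs",
             tracks["track_id"].nunique() if len(tracks) else 0,
             time.perf_counter() - t0)

    if cfg.taper_entry_x is not None and len(tracks):
        kept = []
        for _, grp in tracks.groupby("track_id"):
            clipped = channel_entry_filter(grp, cfg.taper_entry_x)
            if clipped is not None and len(clipped) >= cfg.min_track_length:
                kept.append(clipped)
        tracks = (pd.concat(kept, ignore_index=True)
                  if kept else tracks.iloc[0:0])

    tracks = classify_tracks(tracks, min_frames=cfg.min_track_length)
    _, n_overlap = exclude_yellow(tracks)

    metrics = summarize_tracks(tracks, frame_interval=movie.frame_interval)
    ratio_rows = []
    for tid, grp in tracks.groupby("track_id"):
        rec = per_cell_ratios(grp, frame_interval=movie.frame_interval,
                              min_steps=cfg.min_phase_steps)
        if rec is not None:
            ratio_rows.append({
                "track_id": rec.track_id,
                "velocity_ratio_G1_over_SG2": rec.velocity_ratio,
                "persistence_ratio_G1_over_SG2": rec.persistence_ratio,
                "n_steps_G1": rec.n_steps_G1, "n_steps_SG2": rec.n_steps_SG2,
            })
    ratios = pd.DataFrame(ratio_rows, columns=[
        "track_id", "velocity_ratio_G1_over_SG2",
        "persistence_ratio_G1_over_SG2", "n_steps_G1", "n_steps_SG2"])
    return PipelineResult(detections=detections, tracks=tracks,
                          track_metrics=metrics, ratios=ratios,
                          masks=masks, n_excluded_overlap=n_overlap)


def load_movie(config: PipelineConfig) -> MovieStack:
    """Read channel TIFFs; frame counts must agree across channels."""
    for name, path in (("red", config.red_path), ("green", config.green_path)):
        if not path or not Path(path).exists():
            raise InputError(f"missing {name} channel TIFF: {path!r}")
    red = read_stack(config.red_path)
    green = read_stack(config.green_path)
    if red.shape != green.shape:
        raise InputError(
            f"channel frame-count/shape mismatch: red {red.shape} vs "
            f"green {green.shape}")
    trans = None
    if config.trans_path:
        if not Path(config.trans_path).exists():
            raise InputError(f"missing trans channel TIFF: {config.trans_path!r}")
        trans = read_stack(config.trans_path)
        if trans.shape != red.shape:
            raise InputError(
                f"channel frame-count/shape mismatch: trans {trans.shape} vs "
                f"red {red.shape}")
    return MovieStack(red=red.astype(np.float32),
                      green=green.astype(np.float32),
                      trans=(trans.astype(np.float32) if trans is not None
                             else np.zeros_like(red, dtype=np.float32)),
                      pixel_size=config.pixel_size,
                      frame_interval=config.frame_interval)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes all artifacts plus a manifest."""
    cfg = config.validate()
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level)
    movie = load_movie(cfg)
    if not cfg.trans_path:
        cfg.use_phase_channel = False
    result = analyze_movie(movie, cfg)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels(out / "label_masks.tif", result.masks)
    write_table(out / "detections.csv", result.detections)
    write_table(out / "tracks.csv", result.tracks)
    write_table(out / "track_metrics.csv", result.track_metrics)
    write_table(out / "per_cell_ratios.csv", result.ratios)
    pv = phase_velocity_table(result.tracks, frame_interval=movie.frame_interval)
    write_table(out / "phase_velocities.csv", pv)
    write_manifest(out / "manifest.txt", {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "n_detections": len(result.detections),
        "n_tracks": result.tracks["track_id"].nunique() if len(result.tracks) else 0,
        "n_excluded_overlap": result.n_excluded_overlap,
    })
    (out / "pipeline_config.txt").write_text(to_flat(cfg), encoding="utf-8")
    return result
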