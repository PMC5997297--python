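"""Tracking: pair costs, gates, association optimality and identity quality."""

import itertools
import math

import numpy as np
import pytest

import cycletrack as ct
from cycletrack.tracking import (Detection, adaptive_gate, associate,
                                 associate_dataframe, link_quality, pair_cost)


def det(frame, label, x, y, area=100.0, red=50.0, green=50.0):
    return Detection(frame, label, x, y, area, red, green)


class TestPairCost:
    def test_identical_detection_costs_zero(self):
        a = det(0, 1, 10.0, 10.0)
        b = det(1, 1, 10.0, 10.0)
        assert pair_cost(a, b) == 0.0

    def test_distance_gate_at_twice_max_radius(self):
        a = det(0, 1, 0.0, 0.0, area=math.pi * 25)  # radius 5
        b = det(1, 1, 2.1 * 5.0, 0.0, area=math.pi * 25)
        assert pair_cost(a, b) == math.inf
        c = det(1, 1, 1.9 * 5.0, 0.0, area=math.pi * 25)
        assert math.isfinite(pair_cost(a, c))

    def test_size_gate_at_ninety_percent_change(self):
        a = det(0, 1, 0.0, 0.0, area=100.0)
        b = det(1, 1, 0.0, 0.0, area=5.0)     # 95% difference
        assert pair_cost(a, b) == math.inf
        c = det(1, 1, 0.0, 0.0, area=20.0)    # 80% difference
        assert math.isfinite(pair_cost(a, c))

    def test_same_frame_rejected(self):
        with pytest.raises(ct.InputError):
            pair_cost(det(3, 1, 0, 0), det(3, 2, 0, 0))


class TestAdaptiveGate:
    def test_candidates_inside_base_gate_keep_scale_one(self):
        target = det(0, 1, 0.0, 0.0)
        pool = [det(1, i, 1.0 * i, 0.0) for i in range(10)]
        assert adaptive_gate(target, pool) == 1.0

    def test_gate_expands_until_five_candidates(self):
        target = det(0, 1, 0.0, 0.0, area=math.pi)  # radius 1
        pool = [det(1, i, 3.0 + 0.01 * i, 0.0, area=math.pi) for i in range(5)]
        scale = adaptive_gate(target, pool)
        assert scale > 1.0
        assert all(math.isfinite(pair_cost(target, p, gate_scale=scale))
                   for p in pool)

    def test_exhausted_pool_stops_expansion(self):
        target = det(0, 1, 0.0, 0.0, area=math.pi)
        pool = [det(1, i, 5.0 + i, 0.0, area=math.pi) for i in range(3)]
        scale = adaptive_gate(target, pool)
        dists = [5.0 + i for i in range(3)]
        assert all(d <= scale * 2.0 for d in dists)


def _random_instance(rng, n_cells=None, n_frames=None):
    """Random tracking instance: constant cell count, similar areas.

    With at most four cells per frame the adaptive gate opens every spatial
    gate (pool < 5), and areas within 10% keep the size gate open, so all
    pair costs are finite and the globally optimal solution is a perfect
    matching per consecutive frame pair (a gap link would lose one link).
    """
    n_cells = n_cells or int(rng.integers(1, 5))
    n_frames = n_frames or int(rng.integers(2, 6))
    dets = []
    x = rng.uniform(0, 50, n_cells)
    y = rng.uniform(0, 50, n_cells)
    for f in range(n_frames):
        x = x + rng.normal(0, 3, n_cells)
        y = y + rng.normal(0, 3, n_cells)
        for i in range(n_cells):
            dets.append(Detection(
                f, i + 1, float(x[i]), float(y[i]),
                float(rng.uniform(95, 105)),
                float(rng.uniform(40, 60)), float(rng.uniform(40, 60))))
    return dets


def _oracle_min_cost(dets, weights=(1.0, 1.0, 1.0)):
    """Exhaustive per-pair enumeration of max-cardinality min-cost matchings.

    Valid when every pair cost is finite and the per-frame cell count is
    constant (asserted): then the lexicographic optimum (most links, then
    least cost) decomposes over consecutive frame pairs and is found by
    enumerating all permutations.
    """
    by_frame = {}
    for d in dets:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)
    counts = {len(v) for v in by_frame.values()}
    assert len(counts) == 1
    total = 0.0
    for fa, fb in zip(frames[:-1], frames[1:]):
        A, B = by_frame[fa], by_frame[fb]
        best = math.inf
        for perm in itertools.permutations(range(len(B))):
            c = 0.0
            for i, j in enumerate(perm):
                gate = adaptive_gate(A[i], B, weights=weights)
                pc = pair_cost(A[i], B[j], gate_scale=gate, weights=weights)
                assert math.isfinite(pc)
                c += pc
            best = min(best, c)
        total += best
    return total


class TestAssociate:
    def test_single_cell_single_track(self):
        dets = [det(f, 1, 10.0 + f, 20.0) for f in range(10)]
        result = associate(dets)
        assert len(result.tracks) == 1
        assert len(result.tracks[0]) == 10

    def test_matches_exhaustive_oracle(self):
        """Total association cost equals brute-force optimum on 1000 random
        instances with <= 4 cells x <= 5 frames."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            dets = _random_instance(rng)
            result = associate(dets)
            oracle = _oracle_min_cost(dets)
            assert result.total_cost == pytest.approx(oracle, abs=1e-9)

    def test_two_separated_cells_no_switches(self, clean_scene):
        cfg, truth, movie = clean_scene
        _, detections = ct.segment_movie(movie)
        tracks = associate_dataframe(detections, pixel_size=cfg.pixel_size)
        quality = link_quality(tracks, truth)
        assert (quality.switches == 0).all()
        assert (quality.purity == 1.0).all()

    def test_gap_bridging_across_missed_detection(self):
        dets = [det(f, 1, 10.0 + f, 20.0) for f in (0, 1, 3, 4)]
        result = associate(dets, window=3)
        assert len(result.tracks) == 1
        frames = [d.frame for d in result.tracks[0].detections]
        assert frames == [0, 1, 3, 4]

    def test_gap_beyond_window_starts_new_track(self):
        dets = [det(f, 1, 10.0, 20.0) for f in (0, 1, 5, 6)]
        result = associate(dets, window=3)
        assert len(result.tracks) == 2

    def test_permutation_invariance(self, rng):
        dets = _random_instance(rng, n_cells=4, n_frames=5)
        shuffled = list(dets)
        rng.shuffle(shuffled)
        a = associate(dets)
        b = associate(shuffled)
        sig_a = sorted(tuple((d.frame, d.label_id) for d in tr.detections)
                       for tr in a.tracks)
        sig_b = sorted(tuple((d.frame, d.label_id) for d in tr.detections)
                       for tr in b.tracks)
        assert sig_a == sig_b

    def test_no_detection_used_twice(self, noisy_scene):
        cfg, truth, movie = noisy_scene
        _, detections = ct.segment_movie(movie)
        tracks = associate_dataframe(detections, pixel_size=cfg.pixel_size)
        used = list(zip(tracks.frame, tracks.label_id))
        assert len(used) == len(set(used))

    def test_purity_on_default_scene(self):
        """20 cells, 100 frames at default noise: purity >= 0.95."""
        cfg = ct.SceneConfig(n_cells=20, n_frames=100, mode="channel",
                             image_shape=(1024, 512), seed=17)
        truth, movie = ct.simulate_scene(cfg)
        _, detections = ct.segment_movie(movie)
        tracks = associate_dataframe(detections, pixel_size=cfg.pixel_size,
                                     min_track_length=5)
        quality = link_quality(tracks, truth)
        assert quality.purity.min() >= 0.95


class TestLinkQuality:
    def test_merged_track_purity_bounded(self, clean_scene):
        cfg, truth, movie = clean_scene
        _, detections = ct.segment_movie(movie)
        tracks = associate_dataframe(detections, pixel_size=cfg.pixel_size)
        two = tracks[tracks.track_id.isin(tracks.track_id.unique()[:2])].copy()
        sizes = two.groupby("track_id").size()
        two["track_id"] = 0  # deliberately merge two cells into one track
        quality = link_quality(two, truth)
        assert quality.purity.iloc[0] <= sizes.max() / sizes.sum() + 1e-9
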