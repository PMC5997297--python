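"""Classify cell-cycle phases along tracks and compare migration by phase.

Each frame of a track is G1 while the mean red intensity exceeds 50% of the
track's maximum red, S/G2 afterwards; frames where both reporters exceed
half their maxima are the early-S overlap and are excluded from
phase-stratified statistics.  The scene below reproduces the contact
guidance + EGF gradient condition in which G1 cells move ~20% faster.
"""

import cycletrack as ct

config = ct.contact_guidance_egf_config(seed=1)
config.n_cells, config.n_frames = 20, 100      # scaled-down demo
config.image_shape = (768, 512)
truth, movie = ct.simulate_scene(config)

result = ct.analyze_movie(movie)
print(f"{result.tracks.track_id.nunique()} tracks; "
      f"{result.n_excluded_overlap} overlap frames excluded")

excess, lo, hi = ct.g1_velocity_excess_percent(
    result.tracks, frame_interval=config.frame_interval, seed=1)
print(f"G1 velocity excess over S/G2: {excess:.1f}% "
      f"(bootstrap 95% CI [{lo:.1f}, {hi:.1f}]%)")
# the generator's speed ratio is 1.2, so ~20% is the expected recovery

pv = ct.phase_velocity_table(result.tracks,
                             frame_interval=config.frame_interval)
g1 = pv.loc[pv.phase == "G1", "velocity_um_min"]
sg2 = pv.loc[pv.phase == "SG2", "velocity_um_min"]
cmp_res = ct.compare_groups(g1, sg2)
print(f"G1 {cmp_res.mean_a:.3f} +/- {cmp_res.sem_a:.3f} um/min vs "
      f"S/G2 {cmp_res.mean_b:.3f} +/- {cmp_res.sem_b:.3f} um/min: "
      f"t = {cmp_res.t:.2f}, p = {cmp_res.p:.2e} {cmp_res.stars}")

ratios = result.ratios
if len(ratios):
    med = ratios.velocity_ratio_G1_over_SG2.median()
    print(f"per-cell G1:S/G2 velocity ratio (median of {len(ratios)} cells "
          f"tracked through the switch): {med:.2f}")
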