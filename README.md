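# cycletrack

Cell-cycle-resolved migration analysis for FUCCI time-lapse microscopy.

Directed cancer-cell migration — contact guidance along microchannel walls
or aligned collagen fibers, and chemotaxis up a growth-factor gradient — can
depend on where a cell is in its cycle. Quantifying that requires an imaging
pipeline that (i) segments cells from two FUCCI reporter channels plus a
transmitted-light channel, (ii) links detections across frames into tracks,
(iii) labels each tracked frame G1 or S/G2 from the reporter intensities,
and (iv) turns tracks into migration statistics stratified by phase.
`cycletrack` implements that pipeline, together with the two supporting
models such experiments lean on: a diffusion model of the chemoattractant
gradient in the microchannel device, and an orientation analysis for
collagen-fiber images. A ground-truthed synthetic-scene generator renders
movies with known trajectories, phases and noise so every stage is testable
without any raw data.

It is a library first: `import cycletrack` and compose the stages, or run
the thin `cycletrack` CLI (`simulate`, `gradient`, `segment`, `track`,
`phase`, `stats`, `fibers`, `run-all`) for file-based workflows.

## Core methods

**Segmentation** — each fluorescence frame is denoised as
`median₃ₓ₃(I) − G_σ(I)` (the Gaussian low-pass, kernel 10% of the image
side, estimates the slow background; the median removes shot noise), then
Otsu-thresholded on the pixelwise max of red and green so cells stay
detectable through the reporter handoff. The transmitted-light foreground
(pixels > 1 sd from the frame median, unioned with an Otsu-thresholded
Sobel gradient image) is intersected with the fluorescence components to
form the final label mask. Mean reporter intensities are measured on the
raw channels.

**Tracking** — multi-frame association over a sliding 3-frame window. The
pair cost combines normalised displacement, relative area change and
relative intensity change; pairs farther apart than twice the larger
equivalent radius, or differing in area by more than 90%, are gated to
infinite cost. The spatial gate relaxes by 1.5× until at least five
candidates are admitted. Links are chosen per frame by minimum-cost
maximum-cardinality assignment; a link skipping one frame pays a 1.25×
penalty. On small instances the tracker's total cost equals an
exhaustive-search oracle.

**Phase classification** — along a track, a frame is G1 while
`red > 0.5 · max(red)` (track-level, retrospective maximum) and S/G2
otherwise; frames where green is additionally above half its track maximum
are the early-S "yellow" overlap and are excluded from phase-stratified
statistics. Snapshot (population) classification thresholds each channel
at half its movie-level 99th percentile.

**Migration statistics** — instantaneous velocity `‖Δx‖/Δt` (µm/min),
persistence = net displacement / path length ∈ [0, 1], per-cell G1:S/G2
metric ratios for cells tracked through the switch, and equal-variance
two-tailed t-tests with mean ± SEM summaries and significance stars.

**Gradient model** — ∂C/∂t = D∇²C on the 850 × 10 µm channel rectangle with
a constant-concentration source edge, sink outflux k·C (Robin), no-flux
walls, D = 0.5×10⁻⁴ cm²/s; backward-Euler finite differences verified
against the 1D closed form C(x) = C(0) + kC₀/(D + kL)·x.

**Fiber orientation** — structure-tensor orientation field
(Gaussian-derivative gradients, coherence-filtered), axial circular
statistics on doubled angles, and a Rayleigh uniformity test to separate
random from aligned gels.

## Worked example

```python
import cycletrack as ct

config = ct.contact_guidance_egf_config(seed=1)   # 10 µm channels + gradient
config.n_cells, config.n_frames = 20, 100         # scaled-down demo
config.image_shape = (768, 512)
truth, movie = ct.simulate_scene(config)
result = ct.analyze_movie(movie)
excess, lo, hi = ct.g1_velocity_excess_percent(result.tracks, seed=1)
```

Output (see `examples/04_cell_cycle_migration.py`):

```
20 tracks; 14 overlap frames excluded
G1 velocity excess over S/G2: 22.0% (bootstrap 95% CI [17.0, 27.7]%)
G1 0.539 +/- 0.004 um/min vs S/G2 0.442 +/- 0.004 um/min: t = 18.03, p = 2.15e-67 ***
per-cell G1:S/G2 velocity ratio (median of 20 cells tracked through the switch): 1.26
```

The generator gave G1 cells a 1.2× speed advantage; the full
segment → track → classify → measure pipeline recovers a ~20% velocity
excess with the early-S overlap frames excluded, and the per-cell ratio
(each cell its own control, removing intercellular heterogeneity) centres
on the same effect. The other scripts under `examples/` demonstrate scene
generation, gradient stability, tracking quality against ground truth, and
fiber-alignment verdicts, each printing the numbers it computes.

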