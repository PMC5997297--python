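# Methods

This note records the models, parameter choices and numerical decisions
behind `cycletrack`, and what the synthetic validation does and does not
establish about real data.

## Synthetic scenes

### Motility model

Cells follow a discrete-time persistent random walk. Per 10-minute step the
heading gains Gaussian noise (sd `heading_noise_phase`, radians) and the
step length is `speed_phase × frame_interval`, jittered multiplicatively
(Gaussian, sd 10%, clipped at zero). In `channel_chemotaxis` mode the
heading additionally relaxes toward +x by `θ ← θ − b·sin θ` with
`b = chemotaxis_bias ∈ [0, 1]`; b = 0 is a pure persistent walk, b = 1
pins the heading to the channel axis. Channel modes reflect the walker at
the channel walls (and both modes at the field bounds), flipping the
corresponding heading component.

The persistent random walk is the minimal model with independent speed and
persistence knobs, which is exactly what phase-stratified velocity and
persistence statistics need. Defaults: `speed_G1 = 0.6`,
`speed_SG2 = 0.5` µm/min (a 1.2 ratio, the regime of interest for
contact-guided migration; magnitudes typical of mesenchymal breast-cancer
cells), `heading_noise_G1 = 0.3`, `heading_noise_SG2 = 0.5` rad/step,
`chemotaxis_bias = 0.3`.

Two consequences of wall reflection are worth knowing. First, a step whose
chord folds at a wall is shorter than the commanded step length, so
*measured* mean speeds in 10 µm channels sit ~10–15% below the configured
speeds; the compression is common to both phases, so phase *ratios* are
preserved (verified in the tests). Second, reflection at the short field
ends reverses direction without changing speed, so end effects do not bias
velocity statistics (they would bias persistence, which is why persistence
parameter-recovery tests run in large unconfined fields).

### Cell-cycle clock and reporter traces

Each cell cycles G1 (`t_G1` = 10 h) → early-S handoff (`t_overlap` = 2 h) →
S/G2 (`t_SG2` = 10 h) and restarts in G1 without dividing (mitosis is out
of scope; metrics are per-track). Cycle duration for this line is not a
published constant; 22 h keeps both phases represented in a 30 h movie and
the handoff occupancy at 2/22 ≈ 9%. Populations are asynchronous via
uniform per-cell phase offsets.

The red reporter holds at `intensity_peak` through G1 and decays linearly
to zero across the handoff; green rises linearly from zero over the same
window and holds through S/G2. Intensities are evaluated at the frame
exposure midpoint, so a 2 h handoff at 10 min/frame yields exactly 12
dual-signal frames. Motility switches from G1 to S/G2 parameters at the
handoff midpoint — the red half-decay point, i.e. the same landmark a
50%-of-max classifier estimates — reflecting the view that the motility
transition tracks S-phase commitment near the middle of the reporter
overlap rather than its edges.

Note a structural property of the linear crossing ramps: the set where
*both* reporters exceed 50% of their maxima is a single instant, so a
strict 50%/50% overlap rule flags at most the one or two frames around the
midpoint, not the full 12-frame handoff. Overlap exclusion therefore
removes few frames; the dual-signal ("yellow") fraction stays well under
10% of classified cells, consistent with sparse yellow labelling in real
FUCCI populations.

### Rendering

Fluorescence channels are sums of isotropic Gaussian blobs
(sd `blob_radius` = 5 µm ≈ a nuclear FWHM of ~12 µm) scaled by the
reporter trace, plus a smooth background (white noise Gaussian-filtered
with sd 25% of the short image side, computed in Fourier space with
periodic boundaries, rescaled to sd `background_amplitude` and offset by
twice that so it stays non-negative), plus zero-mean Gaussian shot noise.
The transmitted channel is mid-gray with a darker body and thin bright rim
per cell, the same noise model, and dark wall lines in channel modes.
Pixel size 0.65 µm (20× objective scale), x right / y down, 0-based pixel
centres. Identical config + seed reproduces every array bit-for-bit.

Channel geometry: centerlines are laid out at `channel_pitch` (default
30 µm); cells are assigned round-robin, and same-channel cells start in
staggered x slots because cell–cell exclusion is not modelled — without
staggering, overtaking cells merge into single blobs, which no
intensity-based segmenter can split (watershed splitting is likewise out
of scope).

Not modelled: photobleaching, focus drift, collisions, mitotic rounding,
lineage. Passing tests on these scenes therefore demonstrate correctness
of the measurement machinery under the stated imaging physics, not
robustness to those real-world effects.

### Fiber images

Anti-aliased line segments (Gaussian cross-profile, max-composited) with
random centres and lengths 0.3–0.7 of the image side; angles uniform on
[0°, 180°) or normal (µ, σ) folded mod 180°. The drawn angles are returned
as ground truth.

## Gradient model

The chemoattractant obeys ∂C/∂t = D∇²C on the 850 × 10 µm channel
rectangle: source edge fixed at C₀, sink edge outflux k·C, long walls
no-flux, C(t=0) = 0. D = 0.5×10⁻⁴ cm²/s (5×10³ µm²/s). The same quantity
is printed elsewhere in the source literature with µm²/s units — an
internal inconsistency; the cm²/s value is used, and with it
L²/D ≈ 2.4 min, so the profile is at steady state long before the 6–24 h
observation window. The sink coefficient k is a mass-transfer velocity
(µm/s); flux continuity makes 1/s units dimensionally impossible for a
flux k·C. Default k = D/L_res with L_res = 1 mm, i.e. the sink behaves as
a well-mixed ~1 mm reservoir; any fixed k yields a steady state, which is
what the stability claim tests. The steady profile is linear with slope
kC₀/(D + kL); k → ∞ recovers the perfect-sink line.

Discretisation: 5-point graph Laplacian on a 5 µm grid. Omitting links at
the domain edge *is* the no-flux condition and keeps column sums zero, so
a closed box conserves the grid sum of C to machine precision. Default
stepper is backward Euler (Δt = 5 s) with a pre-factorised sparse LU —
unconditionally stable, and its fixed point is the exact discrete steady
state, so steady-state answers are Δt-independent. An explicit scheme is
available for verification and refuses time steps violating
D·Δt/Δx² ≤ 1/4. An explicit default would need Δt ≲ 1.25 ms, ~10⁸ steps
for 24 h — the implicit default is a runtime decision with no accuracy
cost at the times of interest.

"Average gradient steepness" is computed as the mean |∂C/∂x| (central
differences) of the width-averaged profile; with W ≪ L and no-flux walls
the width average matches the 1D problem. An end-to-end line fit would be
an equally defensible reading; both the per-time steepness and the raw
profiles are exposed so either can be formed.

## Segmentation

Denoising follows the two-component noise model (slow background + shot
noise): output = `median₃ₓ₃(I) − G_σ(I)` clipped at zero, with the
Gaussian kernel 10% of the shorter image side (σ = kernel/4, so ±2σ spans
the stated kernel). "Adaptive Otsu" is read as per-frame threshold
recomputation; the threshold is taken on the pixelwise max of the two
denoised FUCCI channels so cells remain detectable mid-handoff. Phase
(transmitted) foreground: |I − median| > 1 frame-sd, unioned with an
Otsu-thresholded Sobel magnitude, holes filled; the median is the
background estimator because it is robust to foreground area. The final
mask intersects fluorescence components with the phase mask pixelwise;
components losing >50% of their area are dropped, and fragments created by
the intersection are re-filtered against the 30 px minimum size
(≈ half a nucleus at defaults). Mean intensities are measured on raw
channels so background subtraction cannot distort classification ratios.

## Tracking

The association cost is a unit-weighted sum of dist/(r_a + r_b),
|Δarea|/max(area), and (|Δred| + |Δgreen|)/(max red + max green) — the
three stated ingredients (location, size/shape, intensity) in
dimensionless, self-normalising form; weights are configurable. Gates:
distance > 2 × max radius (spatial, adaptive ×1.5 growth until ≥5 finite
candidates or the pool is exhausted) and area change > 90% (fixed).

Association is solved per frame by minimum-cost maximum-cardinality
assignment between open track heads (last seen within window − 1 = 2
frames; a skipped frame multiplies the cost by 1.25) and the frame's
detections. A greedy cheapest-edge-first forest was considered and
rejected: it is provably suboptimal on 2×2 counterexamples, whereas the
per-frame optimal assignment matches an exhaustive-search oracle exactly
on all tested small instances (the regression suite checks 1000 of them).
Ties are broken by sorting detections (frame, label), making association
invariant to input order. Tracks shorter than 5 frames are dropped from
downstream statistics.

## Phase classification

Longitudinal rule: G1 iff red > 50% of the track's (retrospective) maximum
red; frames with green additionally above 50% of max green are flagged as
early-S overlap; the switch frame is the first S/G2 frame after a G1 run.
Tracks that never express a reporter above the movie-level snapshot
threshold (half the 99th-percentile detection intensity per channel) are
labelled single-phase wholesale — without this floor, an S/G2-only track's
"maximum red" is background noise and the 50% rule flickers. Tracks
entering the movie mid-handoff have a biased retrospective maximum and a
correspondingly late detected switch; switch-accuracy guarantees
(±1 frame at high SNR) apply to tracks observed with a G1 plateau.

Snapshot rule (population statistics): red-only above threshold → G1,
green-only → S/G2, both → yellow (excluded, counted), neither → unknown.

## Migration statistics

Velocity uses actual elapsed time across occlusion gaps. The persistence
denominator is the total path length (net/path ∈ [0, 1]); reading
"total displacement" as net displacement would make the ratio identically
1. Per-cell ratios use each phase's longest contiguous run (≥ 6 steps,
1-frame gaps bridged, overlap frames excluded) so each cell serves as its
own control. Group comparisons default to the equal-variance Student
t-test (matching the naming convention of the source analyses); Welch is
available via `equal_var=False`. No multiple-testing correction is
applied, matching standard practice for these single-comparison figures.
Population velocity analyses default to per-track means;
`phase_velocity_table` exposes pooled per-step values.

## Fiber orientation

The per-pixel orientation comes from the 2×2 structure tensor built from
Gaussian-derivative gradients (sd 1 px) and smoothed with sd 2 px; the
fiber direction is the eigenvector of the smaller eigenvalue. Gaussian
derivatives matter: nominally equivalent small-kernel derivatives leave an
orientation-dependent bias of a few degrees, while this formulation is
accurate to <0.1° on rendered test patterns. Pixels with coherence
(λ₁ − λ₂)/(λ₁ + λ₂) < 0.2 or anisotropic energy below the median of
retained energies are discarded; remaining angles are weighted by energy.

All statistics treat angles as axial (θ ≡ θ + 180°) by doubling before
circular averaging. The wrapped-normal sd is recovered from the doubled
resultant as σ = √(−ln R̄/2). Uniform-vs-unimodal verdicts use the
Rayleigh test with the standard finite-n approximation; with weights, n is
the Kish effective size. Caveat: pixel-level angle sets are spatially
correlated (hundreds of pixels per fiber), so image-level verdicts should
pass the fiber count as `n_effective`; per-fiber angle lists need no
correction. A fiber-count-free correction (e.g. estimating the
decorrelation area) is a known limitation left open.

## Reproducibility and problem sizes

All randomness flows from explicit seeds through `numpy` generators
(`SeedSequence` spawning per subsystem), and the file pipeline writes a
manifest with the config hash and package version; identical config +
inputs regenerate byte-identical CSVs. The validation suite runs on
scaled-down scenes (256–1856 px fields, 15–120 frames, 5–50 cells) chosen
so the full suite completes in a few minutes; the headline velocity-excess
computation uses the full 50-cell, 120-frame scene with one cell per
channel, whose movie (~1.4 GB as float32) is the largest object the
package allocates.
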