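# Methods

## The measurement

A gliding motility assay inverts the usual motor geometry: kinesin-1 is
bound to a casein-passivated coverslip and fluorescent microtubules are
propelled across it. The observable is the gliding speed of each
filament, estimated from time-lapse fluorescence (default 5 frames/s,
600 frames per region of interest, 16-bit single channel). Because
microtubule ends are not permanently attached to motors, the tracked end
positions carry transient Brownian fluctuation, and filaments
occasionally pause or stall; the pipeline is designed so that neither
corrupts the speed estimate.

## Speed pipeline

For each retained track and each labeled end:

1. **Smoothing.** Each coordinate is convolved with a discrete Gaussian
   of standard deviation σ = 2 s (10 frames at 0.2 s), truncated at
   ±4σ with weights renormalized within the available window. A
   symmetric kernel preserves constant and uniform (affine-in-time)
   motion exactly in the window interior, so smoothing attenuates
   Brownian jitter without biasing steady gliding.
2. **Boundary truncation.** Samples within 5 s of either end of the
   track are dropped. Note the truncation (5 s) is smaller than the
   kernel's 4σ support (8 s), so a thin band of weakly edge-biased
   points survives; its effect on unimodal speed distributions is
   negligible (<0.1% on recovered modes), but it can nudge the argmax
   along *degenerate flat* density tops (see limitations).
3. **Instantaneous speed.** vᵢ = ‖pᵢ₊₁ − pᵢ‖ / Δt in nm/s.
4. **Pooling and KDE mode.** Samples from both ends of all retained
   tracks in an ROI are concatenated and the "most likely speed" is the
   argmax of the Gaussian kernel density d(x) = (1/nh) Σ φ((x−vᵢ)/h)
   with h = 50 nm/s, scanned on a 1 nm/s grid over
   [max(0, min−3h), max+3h] (ties to the smallest speed) and refined
   once by golden-section search within ±1 grid step. The kernel width
   is interpreted as the Gaussian's standard deviation (consistent with
   how the smoothing window is specified); an FWHM interpretation is
   available via `SpeedConfig(bandwidth_is_fwhm=True)`. The mode rather
   than the mean is used because pausing piles mass near zero speed:
   at 15% pause occupancy the mean drops ~15% while the mode stays on
   the moving-speed peak (the pipeline reports both).
5. **Aggregation.** The first 5 ROI estimates of each replicate assay
   are discarded (the slide equilibrates thermally with the objective
   over roughly the first 10 minutes); estimates are matched greedily in
   ascending assay time across assays within ±20 s; matched sets of ≥2
   yield mean and SEM (sample SD with n−1, divided by √n). An ROI's
   assay time is the midpoint of its acquisition window.

Both ends of each track contribute samples by default (doubling n);
midpoint-based speeds are available via `SpeedConfig(use_midpoint=True)`.

## Track retention

Tracks shorter than 100 consecutive frames, or with a median per-frame
segmented area under 55 pixels, are discarded: small filaments cannot be
end-localized precisely and short tracks leave too few samples after
truncation. "Area over a track" is summarized by the median because it
resists single-frame segmentation glitches. Linking is greedy
nearest-centroid with a gate of 3× the expected per-frame advance —
adequate when the gate is far below the inter-filament spacing, which
holds at gliding-assay densities; there is no global assignment and no
gap closing. A track ends when its bounding box comes within 10 px of
the field border (`edge`), when two tracked filaments merge into one
component or claim the same detection (`overlap`; all involved tracks
terminate and are never resumed), when no detection matches
(`disappeared`), or at the end of the stack.

## Image operations

Dead pixels are replaced by the mean of their live 8-neighbors (nearest
live pixel if the whole neighborhood is dead); the repair is idempotent
and exact on uniform frames. Segmentation is a global threshold (Otsu by
default; fixed value for deterministic fixtures) followed by 8-connected
labeling; components under 5 px are discarded as specks — deliberately
far below the 55-px track filter so that retention decisions stay at the
track level. If the thresholded foreground exceeds 20% of the frame the
frame is treated as empty: an Otsu threshold computed on a frame without
filaments lands inside the background noise and floods the frame, and no
real gliding field is 20% filament.

End localization skeletonizes the mask (Zhang thinning, 8-connected),
takes skeleton pixels with exactly one skeleton neighbor as tip
candidates, and selects the two at maximal geodesic separation using a
double breadth-first sweep (exact graph diameter on tree-shaped
skeletons). Because thinning retracts tips by 1–2 px, each tip is then
marched along the mask to its boundary (diagonal step preferred, axis
fallback) before subpixel refinement by the intensity-weighted centroid
of its 5×5 neighborhood. Closed-loop skeletons have no tips; such
objects are flagged degenerate and excluded from tracking.

Filament length is estimated as (convex-hull perimeter of the skeleton
pixel centers)/2; for collinear skeletons the degenerate hull's
perimeter is twice the largest pairwise distance. The estimator is exact
for straight filaments and systematically short for curved ones (the
hull of a concave curve is shorter than the curve) — adequate for
comparing length distributions, not for precision morphometry. On
rendered straight filaments of 3–20 µm it is accurate to ≤10%
(dominated at the short end by threshold erosion of the dim PSF tails).

## Simulator

`simulate_truth` models gliding as a leading tip advancing
max(0, N(v, σ_v))·Δt per frame while moving, with heading diffusing by
N(0, s·advance) — s in rad/µm sets path curvature — and the body
following the tip's accumulated trail at arc length L behind ("train on
track", matching how gliding filaments follow their leading tip rather
than translating rigidly). Pausing is a two-state Markov chain in frame
time (switch probability 1 − e^(−rate·Δt), initial state drawn from the
stationary distribution); detachment is geometric per frame and
truncates the track. Transient Brownian end fluctuation is i.i.d.
N(0, σ_B) per frame per coordinate added to each reported end — the
simplest model of unattached-end wobble; it is not an
Ornstein–Uhlenbeck process and carries no frame-to-frame memory.
Filament lengths are uniform on a configurable range (default 2–21 µm,
the span over which tracked filaments are observed). Initial placement
guarantees the whole body fits in the field for any orientation and
raises a configuration error otherwise.

`render_stack` integrates `photons_per_um`·L photons per frame along the
body polyline, blurs with a Gaussian PSF, adds a constant background,
Poisson-samples each pixel (a `shot_noise=False` hook supports
deterministic tests), clips to the camera bit depth, and zeroes a fixed
random dead-pixel set.

Defaults and what they emulate:

| parameter | default | rationale |
|---|---|---|
| `frame_interval` | 0.2 s | 5 frames/s acquisition |
| `pixel_size` | 133 nm/px | 60× objective on a common EMCCD pixel pitch (needed to give the 55-px area rule a physical scale) |
| `psf_sigma` | 130 nm | Gaussian approximation of a high-NA PSF at rhodamine wavelengths |
| `speed_mean` | 950 nm/s | mid-range gliding speed on good passivations |
| `speed_jitter_sd` | 20 nm/s | small per-frame longitudinal variation |
| `brownian_end_sd` | 50 nm/frame | unattached-end wobble amplitude (no published measurement; a placeholder, not a fit) |
| `pause_on/off_rate` | 0 /s | pausing off by default; recovery harnesses set on = off·ρ/(1−ρ) with mean pause 5 s for occupancy ρ |
| `detach_rate` | 0.002 /s | mean surface lifetime ~500 s |
| `path_turn_sd` | 0.05 rad/µm | gently curved gliding paths |
| `length_range_um` | (2, 21) | observed tracked-length span |

Photobleaching is omitted (illumination in such assays is attenuated to
suppress it); no polymerization dynamics, no temperature dependence, no
multi-channel imaging. The simulator reproduces the *statistical*
features the pipeline must be robust to (Brownian ends, pausing,
detachment, shot noise, dead pixels), not the detailed physics of
motor–filament attachment — so passing recovery tests demonstrates the
estimator chain is unbiased under these noise models, not that it would
be unbiased under, e.g., strongly correlated end fluctuations or drift.

## Recovery harness and problem sizes

`recover_experiment` simulates replicate assays at a known speed at the
track-fixture level (imaging bypassed; the imaging stages are validated
separately on short rendered stacks), shares the ROI acquisition
schedule across assays (one ROI per 150 s, midpoint timestamps) so
cross-assay matching is exact, and reports the grand mean of aggregated
ROI modes next to the pooled plain mean. The standard harness — 3 assays
× 15 ROIs × 10 tracks × 600 frames, 50 nm Brownian end noise — recovers
simulated speeds of 870–970 nm/s with <0.2% bias in ~5 s per condition;
under 15% pause occupancy the mode stays within 1% while the plain mean
drops by roughly the pause fraction. These sizes give mode standard
errors well below the 2% acceptance band while keeping a full recovery
run under a minute.

## Numerical notes and limitations

- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical inputs give
  bit-identical tracks, stacks, and reports.
- KDE mode ties break toward the smallest speed; the golden-section
  refinement only replaces the grid argmax when it strictly increases
  the density.
- At sample separations of exactly 2h the merged KDE peak is
  *quartically* flat; any residual asymmetry (e.g. the surviving
  smoothing edge band) can move the numerical argmax several nm/s along
  the plateau. Irrelevant for unimodal assay data, visible only in
  constructed two-speed mixtures.
- The convex-hull length estimator underestimates curved filaments by
  construction; no correction is applied.
- Greedy linking cannot resolve crossing filaments; crossings terminate
  all involved tracks (`overlap`), which is the conservative choice for
  speed estimation.
- SEM is reported only for matched sets of ≥2 assays; singleton time
  points carry an undefined SEM rather than 0.
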