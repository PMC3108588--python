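# glideassay

Analysis of **kinesin-driven microtubule gliding motility assays**, paired
with a synthetic-assay simulator so that every stage of the analysis can be
validated by parameter recovery — no microscope required.

In a gliding assay, kinesin-1 motors are adsorbed to a passivated coverslip
and propel rhodamine-labeled microtubules across the surface; the gliding
speed (typically ~870–970 nm/s at ~33 °C, depending on the casein fraction
used for passivation) reports motor activity. This package implements the
full measurement chain for time-lapse fluorescence stacks (5 frames/s,
600 frames per ~2-minute region of interest):

1. **Image cleanup & segmentation** — dead-pixel interpolation, global
   (Otsu or fixed) thresholding, 8-connected components with a speck floor.
2. **End localization** — skeletonize each filament mask, take the two
   skeleton tips at maximal geodesic separation, refine each to subpixel
   position by an intensity-weighted centroid.
3. **Tracking** — greedy nearest-centroid linking with a displacement gate;
   tracks terminate at the field edge or on filament overlap. Tracks with
   fewer than 100 consecutive frames or a median segmented area below
   55 px are discarded.
4. **Speed extraction** — end positions are smoothed with a sliding
   Gaussian window (σ = 2 s), points within 5 s of either track end are
   dropped, and instantaneous speed is the distance between consecutive
   smoothed positions divided by the frame interval. All speed samples in
   an ROI are pooled and the **most likely speed** is the mode of a
   Gaussian kernel density estimate,

   d(x) = (1/nh) Σᵢ φ((x − vᵢ)/h),  h = 50 nm/s,

   whose argmax is insensitive to the pausing/stalling episodes that bias
   a plain mean low.
5. **Aggregation** — the first 5 ROI estimates of each replicate assay are
   dropped (thermal equilibration), estimates are matched across assays
   within ±20 s of assay time, and mean ± SEM is reported per time point.
6. **Length estimation** — filament length = (convex-hull perimeter of the
   skeleton)/2, the quick estimator used for length-distribution
   comparisons.

The companion simulator (`glideassay.sim_assay`) generates ground-truth
gliding kinematics — persistent leading-tip paths ("train on track" body
following), per-frame speed jitter, transient Brownian fluctuation of the
ends, two-state Markov pausing, detachment — and renders them into 16-bit
stacks with Gaussian-PSF blur, Poisson shot noise, and dead pixels.

## Worked example

```python
from glideassay import MotilityParams, make_track_fixture, tracks_from_table
from glideassay import filter_tracks, roi_mode_speed

m = MotilityParams(speed_mean=949.0, brownian_end_sd=50.0, detach_rate=0.0)
table = make_track_fixture(m, n_mt=10, n_frames=600, frame_interval=0.2, seed=1)
retained, report = filter_tracks(tracks_from_table(table))
est = roi_mode_speed(retained, frame_interval=0.2)
print(report["retained"], est.n_samples, round(est.mode_nm_s, 1))
```

prints

```
9 9882 948.2
```

— 9 of the 10 simulated tracks pass the retention filter (one filament,
drawn near the short end of the 2–21 µm length range, falls under the
55-px area rule), both ends of each retained track contribute 549 speed
samples (600 frames, minus 5 s trimmed per side, differenced), and the
KDE mode recovers the simulated 949 nm/s gliding speed to under 0.1%
despite 50 nm/frame Brownian end noise.

The numbered drivers under `analysis/` run the same machinery end to end
and write their tables under `results/`:

```bash
python analysis/01_simulate_assay.py    # render a demo ROI stack + truth
python analysis/02_extract_tracks.py    # image pipeline on the demo stack
python analysis/03_speed_recovery.py    # recovery at 949/966/870 nm/s
python analysis/04_aggregate_assays.py  # speed-vs-time table with SEM
```

A `glideassay` CLI (`simulate`, `analyze`, `aggregate`, `recover`) exposes
the same pipeline for shell use; every run writes its resolved
configuration and seed next to its outputs.

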