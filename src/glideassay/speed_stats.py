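"""Gliding-speed pipeline: Gaussian position smoothing, boundary
truncation, instantaneous speed, KDE-mode ("most likely") speed per
region of interest, and cross-assay aggregation.

The KDE mode is used instead of the arithmetic mean because gliding
microtubules transiently pause or stall: pausing piles probability mass
near zero speed and biases the mean low, while the mode of a Gaussian
kernel density estimate (kernel SD 50 nm/s) stays at the moving-speed
peak.  The wide kernel also de-emphasizes small speed shifts from, e.g.,
a varying number of engaged motors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .tracking import Track

__all__ = [
    "SpeedSeries",
    "RoiSpeedEstimate",
    "AssayAggregate",
    "SpeedConfig",
    "gaussian_smooth",
    "truncate_edges",
    "instantaneous_speed",
    "kde_density",
    "most_likely_speed",
    "track_speed_series",
    "roi_mode_speed",
    "aggregate_assays",
]

KDE_BANDWIDTH_DEFAULT = 50.0    # nm/s, Gaussian kernel SD
SMOOTH_SIGMA_S_DEFAULT = 2.0    # s
TRIM_S_DEFAULT = 5.0            # s
TIME_TOL_S_DEFAULT = 20.0       # s
DROP_FIRST_DEFAULT = 5


@dataclass(frozen=True)
class SpeedConfig:
    """Tunable parameters of the speed pipeline.

    ``bandwidth_is_fwhm`` reinterprets the kernel width as full width at
    half maximum instead of the default standard deviation.
    ``use_midpoint`` derives speeds from the filament midpoint instead
    of pooling both end trajectories.
    """

    sigma_s: float = SMOOTH_SIGMA_S_DEFAULT
    trim_s: float = TRIM_S_DEFAULT
    bandwidth: float = KDE_BANDWIDTH_DEFAULT
    bandwidth_is_fwhm: bool = False
    grid_step: float = 1.0
    use_midpoint: bool = False

    @property
    def kernel_sd(self) -> float:
        if self.bandwidth_is_fwhm:
            return self.bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return self.bandwidth


@dataclass
class SpeedSeries:
    """Smoothed, truncated instantaneous speeds for one end of one track."""

    track_id: int
    end_label: str
    times: np.ndarray       # (m,) s, midpoint between consecutive samples
    speeds: np.ndarray      # (m,) nm/s, nonnegative
    short_track: bool = False


@dataclass
class RoiSpeedEstimate:
    """KDE-mode speed of one region of interest."""

    roi_id: int
    assay_id: int
    assay_time_s: float
    mode_nm_s: float | None
    n_tracks: int
    n_samples: int
    bandwidth: float = KDE_BANDWIDTH_DEFAULT

    @property
    def no_motility(self) -> bool:
        return self.mode_nm_s is None


@dataclass
class AssayAggregate:
    """Mean +/- SEM of ROI modes matched across replicate assays."""

    assay_time_s: float
    mean_nm_s: float
    sem_nm_s: float | None
    n_assays: int


def gaussian_smooth(positions: np.ndarray, sigma_s: float,
                    frame_interval: float, times: np.ndarray | None = None) -> np.ndarray:
    """Smooth an (n, 2) position series with a sliding Gaussian window.

    The discrete kernel has standard deviation ``sigma_s /
    frame_interval`` frames, truncated at +/-4 sigma with weights
    renormalized to sum to one within the available window; the
    resulting edge bias is removed downstream by boundary truncation.
    """
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) position series")
    if times is not None:
        dt = np.diff(np.asarray(times, dtype=float))
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform time spacing")
    if sigma_s == 0:
        return xy.copy()
    sigma = sigma_s / frame_interval
    num = gaussian_filter1d(xy, sigma, axis=0, mode="constant", cval=0.0, truncate=4.0)
    den = gaussian_filter1d(np.ones(xy.shape[0]), sigma, mode="constant", cval=0.0, truncate=4.0)
    return num / den[:, None]


def truncate_edges(times: np.ndarray, values: np.ndarray,
                   trim_s: float = TRIM_S_DEFAULT) -> tuple[np.ndarray, np.ndarray, bool]:
    """Drop samples within ``trim_s`` of either end of the series.

    Returns ``(times, values, short_flag)``; a series whose duration is
    <= 2*trim_s empties out and is flagged short.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values)
    if t[-1] - t[0] <= 2 * trim_s:
        return t[:0], v[:0], True
    keep = (t >= t[0] + trim_s) & (t <= t[-1] - trim_s)
    return t[keep], v[keep], False


def instantaneous_speed(positions: np.ndarray, frame_interval: float) -> np.ndarray:
    """Euclidean distance between consecutive positions / frame interval."""
    xy = np.asarray(positions, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need >= 2 positions")
    return np.linalg.norm(np.diff(xy, axis=0), axis=1) / frame_interval


def kde_density(samples: np.ndarray, bandwidth: float):
    """Gaussian kernel density over speed samples.

    Returns a vectorized callable d(x) = (1/(n h)) sum_i phi((x - s_i)/h)
    with phi the standard normal density; d integrates to one.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 1:
        raise ValueError("need at least one sample")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    norm = s.size * bandwidth * math.sqrt(2.0 * math.pi)

    def density(x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        out = np.empty(xv.shape, dtype=float)
        step = max(1, int(4e6 / max(s.size, 1)))
        for i in range(0, xv.size, step):
            z = (xv[i:i + step, None] - s[None, :]) / bandwidth
            out[i:i + step] = np.exp(-0.5 * z * z).sum(axis=1)
        out /= norm
        return out[0] if scalar else out

    return density


def _golden_max(f, a: float, b: float, tol: float = 1e-6) -> float:
    """Golden-section search for the maximum of f on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def most_likely_speed(samples: np.ndarray, bandwidth: float = KDE_BANDWIDTH_DEFAULT,
                      grid_step: float = 1.0) -> float:
    """Mode of the Gaussian KDE over the speed samples.

    The density is scanned on the grid [max(0, min - 3h), max + 3h] with
    step ``grid_step`` (ties broken toward the smallest speed), then
    refined once by golden-section search within +/- one grid step.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("no speed samples")
    d = kde_density(s, bandwidth)
    lo = max(0.0, s.min() - 3.0 * bandwidth)
    hi = s.max() + 3.0 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    dens = d(grid)
    best = float(grid[int(np.argmax(dens))])   # first occurrence = smallest
    refined = _golden_max(d, max(lo, best - grid_step), min(hi, best + grid_step))
    return refined if d(refined) > d(best) else best


def track_speed_series(track: Track, frame_interval: float,
                       cfg: SpeedConfig = SpeedConfig()) -> list[SpeedSeries]:
    """Smooth -> truncate -> instantaneous speed for each end of a track.

    By default both labeled ends contribute a series (both are tracked,
    and pooling them doubles the sample count); with
    ``cfg.use_midpoint`` a single series from the filament midpoint is
    returned instead.  Short tracks (duration <= 2*trim) yield flagged,
    empty series.
    """
    times = np.asarray(track.frames, dtype=float) * frame_interval
    if cfg.use_midpoint:
        sources = [("midpoint", (track.end_positions("A") + track.end_positions("B")) / 2.0)]
    else:
        sources = [("A", track.end_positions("A")), ("B", track.end_positions("B"))]
    out = []
    for label, xy in sources:
        sm = gaussian_smooth(xy, cfg.sigma_s, frame_interval, times=times)
        t2, xy2, short = truncate_edges(times, sm, cfg.trim_s)
        if short or len(t2) < 2:
            out.append(SpeedSeries(track.track_id, label, times[:0], times[:0], short_track=True))
            continue
        v = instantaneous_speed(xy2, frame_interval)
        out.append(SpeedSeries(track.track_id, label, (t2[:-1] + t2[1:]) / 2.0, v))
    return out


def roi_mode_speed(tracks: list[Track], frame_interval: float, roi_id: int = 0,
                   assay_id: int = 0, assay_time_s: float = 0.0,
                   cfg: SpeedConfig = SpeedConfig()) -> RoiSpeedEstimate:
    """Concatenate speed samples of all retained tracks in one ROI and
    extract the most likely speed.

    An ROI whose tracks are all filtered out or too short is marked
    no-motility (``mode_nm_s`` is None) — as happens in assays on poor
    passivations.
    """
    samples = []
    n_tracks = 0
    for tr in tracks:
        series = track_speed_series(tr, frame_interval, cfg)
        good = [s.speeds for s in series if not s.short_track and s.speeds.size]
        if good:
            n_tracks += 1
            samples.extend(good)
    if not samples:
        return RoiSpeedEstimate(roi_id, assay_id, assay_time_s, None, 0, 0, cfg.kernel_sd)
    pooled = np.concatenate(samples)
    mode = most_likely_speed(pooled, cfg.kernel_sd, cfg.grid_step)
    return RoiSpeedEstimate(roi_id, assay_id, assay_time_s, mode,
                            n_tracks, pooled.size, cfg.kernel_sd)


def aggregate_assays(estimates_per_assay: list[list[RoiSpeedEstimate]],
                     time_tol_s: float = TIME_TOL_S_DEFAULT,
                     drop_first: int = DROP_FIRST_DEFAULT) -> list[AssayAggregate]:
    """Match ROI estimates across replicate assays and average them.

    The first ``drop_first`` estimates of every assay are removed (the
    slide is still equilibrating thermally with the objective early in
    an assay).  Estimates are then matched greedily in ascending time:
    the earliest unmatched estimate recruits, from every other assay,
    its nearest unmatched estimate within ``+/- time_tol_s``.  Matched
    sets of size >= 2 yield mean and SEM (sample SD with n-1 / sqrt(n));
    singletons are emitted with undefined SEM.
    """
    pools: list[list[RoiSpeedEstimate]] = []
    for assay in estimates_per_assay:
        kept = sorted((e for e in assay if not e.no_motility), key=lambda e: e.assay_time_s)
        pools.append(kept[drop_first:])
    out: list[AssayAggregate] = []
    used = [set() for _ in pools]
    while True:
        seed_at = None
        for ai, pool in enumerate(pools):
            for j, e in enumerate(pool):
                if j in used[ai]:
                    continue
                if seed_at is None or e.assay_time_s < seed_at[2]:
                    seed_at = (ai, j, e.assay_time_s)
                break
        if seed_at is None:
            break
        ai, j, t0 = seed_at
        used[ai].add(j)
        members = [pools[ai][j]]
        for bi, pool in enumerate(pools):
            if bi == ai:
                continue
            cand = [(abs(e.assay_time_s - t0), k) for k, e in enumerate(pool)
                    if k not in used[bi] and abs(e.assay_time_s - t0) <= time_tol_s]
            if cand:
                _, k = min(cand)
                used[bi].add(k)
                members.append(pool[k])
        modes = np.array([m.mode_nm_s for m in members], dtype=float)
        t = float(np.mean([m.assay_time_s for m in members]))
        if len(members) >= 2:
            sem = float(np.std(modes, ddof=1) / math.sqrt(len(members)))
        else:
            sem = None
        out.append(AssayAggregate(t, float(modes.mean()), sem, len(members)))
    out.sort(key=lambda a: a.assay_time_s)
    return out
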