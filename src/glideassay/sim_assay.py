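"""Synthetic gliding-motility-assay generator.

Kinesin motors bound to a passivated coverslip propel fluorescent
microtubules across the surface.  This module simulates that process at
two levels:

1. ``simulate_truth`` produces ground-truth kinematics: each filament's
   leading tip advances along a persistent random path ("train on track"
   -- the body follows the trail laid down by the tip), with optional
   two-state pausing, detachment, per-frame speed jitter, and transient
   Brownian fluctuation of the unattached ends.
2. ``render_stack`` turns ground-truth tracks into a noisy fluorescence
   time-lapse: line-integrated photon flux through a Gaussian PSF,
   Poisson shot noise, a constant background, camera bit-depth clipping,
   and a fixed set of dead pixels.

``make_track_fixture`` bypasses imaging entirely and emits the truth in
the track-table schema, so the speed pipeline can be exercised quickly
and in isolation.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MotilityParams",
    "ImagingParams",
    "TruthTrack",
    "simulate_truth",
    "render_stack",
    "make_track_fixture",
    "TRACK_COLUMNS",
]

#: canonical track-table schema shared by the simulator, the tracker and
#: the speed pipeline
TRACK_COLUMNS = ["mt_id", "end_label", "frame", "time_s", "x_nm", "y_nm", "state", "area_px"]


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class MotilityParams:
    """Ground-truth kinematic parameters of gliding filaments.

    Parameters
    ----------
    speed_mean : float
        Mean gliding speed while moving, nm/s.
    speed_jitter_sd : float
        Per-frame longitudinal speed variation, nm/s.
    brownian_end_sd : float
        Per-frame i.i.d. Gaussian displacement (nm, per coordinate)
        added independently to each reported end position; models the
        transient Brownian fluctuation of ends not currently bound to a
        motor.
    pause_on_rate, pause_off_rate : float
        Rates (1/s) of the two-state moving<->paused Markov chain.
    detach_rate : float
        Rate (1/s) at which a filament detaches from the surface;
        detachment truncates its track.
    path_turn_sd : float
        Heading diffusion of the leading tip, radians per micrometre
        advanced; sets path curvature.
    length_range_um : tuple
        (min, max) filament length in micrometres, sampled uniformly.
    """

    speed_mean: float = 950.0
    speed_jitter_sd: float = 20.0
    brownian_end_sd: float = 50.0
    pause_on_rate: float = 0.0
    pause_off_rate: float = 0.0
    detach_rate: float = 0.002
    path_turn_sd: float = 0.05
    length_range_um: tuple[float, float] = (2.0, 21.0)

    def __post_init__(self) -> None:
        for name in ("speed_mean", "speed_jitter_sd", "brownian_end_sd",
                     "pause_on_rate", "pause_off_rate", "detach_rate", "path_turn_sd"):
            _check_nonneg(name, getattr(self, name))
        lo, hi = self.length_range_um
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or lo > hi:
            raise ValueError(f"length_range_um must satisfy 0 <= min <= max, got {self.length_range_um!r}")


@dataclass(frozen=True)
class ImagingParams:
    """Optics and camera settings used for rendering and analysis.

    The acquisition defaults mirror a typical EMCCD gliding-assay setup:
    5 frames/s, 133 nm pixels (60x objective on a common EMCCD pixel
    pitch), 16-bit counts.
    """

    pixel_size: float = 133.0       # nm/px
    frame_interval: float = 0.2     # s
    field_size: tuple[int, int] = (512, 512)  # (height, width) px
    psf_sigma: float = 130.0        # nm
    photons_per_um: float = 2000.0  # photons per um of filament per frame
    background_mean: float = 10.0   # photons/px
    dead_pixel_fraction: float = 0.001
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not (0 <= self.dead_pixel_fraction < 1):
            raise ValueError("dead_pixel_fraction must be in [0, 1)")
        _check_nonneg("psf_sigma", self.psf_sigma)
        _check_nonneg("photons_per_um", self.photons_per_um)
        _check_nonneg("background_mean", self.background_mean)
        if self.bit_depth < 8:
            raise ValueError("bit_depth must be >= 8")

    @property
    def field_nm(self) -> tuple[float, float]:
        """Field extent (height, width) in nm, pixel centers at integer*pixel_size."""
        h, w = self.field_size
        return (h - 1) * self.pixel_size, (w - 1) * self.pixel_size


@dataclass
class TruthTrack:
    """Ground truth for one simulated microtubule.

    ``leading``/``trailing`` are the *reported* end positions including
    Brownian end fluctuation; ``path_leading``/``path_trailing`` are the
    noise-free positions on the gliding path.  ``path_xy``/``path_s``
    store the full tip polyline and its cumulative arc length so the
    renderer can integrate fluorescence along the filament body.
    """

    mt_id: int
    length_um: float
    times: np.ndarray           # (n,) s, strictly increasing, constant spacing
    leading: np.ndarray         # (n, 2) nm, reported (noisy)
    trailing: np.ndarray        # (n, 2) nm, reported (noisy)
    states: np.ndarray          # (n,) str in {"moving", "paused"}
    path_leading: np.ndarray = field(repr=False, default=None)
    path_trailing: np.ndarray = field(repr=False, default=None)
    path_xy: np.ndarray = field(repr=False, default=None)   # (m, 2) tip polyline incl. initial tail
    path_s: np.ndarray = field(repr=False, default=None)    # (m,) cumulative arc length, nm
    tip_s: np.ndarray = field(repr=False, default=None)     # (n,) tip arc position per frame, nm

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _markov_states(rng: np.random.Generator, n: int, p_pause: float, p_resume: float,
                   start_stationary: bool = True) -> np.ndarray:
    """Two-state chain in discrete frame time; True = paused."""
    paused = np.zeros(n, dtype=bool)
    denom = p_pause + p_resume
    state = False
    if start_stationary and denom > 0:
        state = rng.random() < p_pause / denom
    u = rng.random(n)
    for i in range(n):
        paused[i] = state
        if state:
            state = not (u[i] < p_resume)
        else:
            state = u[i] < p_pause
    return paused


def simulate_truth(motility: MotilityParams, imaging: ImagingParams,
                   n_mt: int, n_frames: int, seed: int) -> list[TruthTrack]:
    """Simulate ground-truth gliding tracks.

    The leading tip advances ``max(0, N(speed_mean, speed_jitter_sd)) *
    frame_interval`` per frame while moving (0 while paused), its heading
    diffusing by ``N(0, path_turn_sd * advance_um)`` per frame.  The
    trailing end follows the tip's accumulated path at arc length
    ``length_um`` behind.  Independent ``N(0, brownian_end_sd)``
    displacement is then added to each reported end coordinate.
    Detachment is tested per frame and truncates the track.

    Returns a list of :class:`TruthTrack`; identical inputs give
    bit-identical output.
    """
    if n_mt < 1:
        raise ValueError("n_mt must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    dt = imaging.frame_interval
    h_nm, w_nm = imaging.field_nm
    lo_um, hi_um = motility.length_range_um
    # central placement box: keep starting filaments away from the border
    margin = 0.25
    if w_nm <= 0 or h_nm <= 0:
        raise ValueError("field too small to place any filament")

    p_pause = 1.0 - math.exp(-motility.pause_on_rate * dt)
    p_resume = 1.0 - math.exp(-motility.pause_off_rate * dt)
    p_detach = 1.0 - math.exp(-motility.detach_rate * dt)

    tracks: list[TruthTrack] = []
    for mt_id, rng in enumerate(np.random.default_rng(seed).spawn(n_mt)):
        length_um = float(rng.uniform(lo_um, hi_um))
        length_nm = length_um * 1000.0
        # place the filament center so the whole body fits regardless of
        # orientation; fall back to a thinner margin for long filaments
        half = length_nm / 2.0
        pads = []
        for extent in (w_nm, h_nm):
            pad = max(margin * extent, half * 1.05)
            if 2 * pad >= extent:
                pad = half * 1.05
            if 2 * pad >= extent:
                raise ValueError(
                    f"field too small to place a {length_um:.1f} um filament")
            pads.append(pad)
        heading0 = rng.uniform(0.0, 2.0 * math.pi)
        cx = rng.uniform(pads[0], w_nm - pads[0])
        cy = rng.uniform(pads[1], h_nm - pads[1])
        x0 = cx + half * math.cos(heading0)
        y0 = cy + half * math.sin(heading0)

        # detachment: geometric in frame count (frame index at which the
        # filament leaves; n_frames means it survives the whole stack)
        if p_detach > 0:
            n_keep = min(n_frames, 1 + int(rng.geometric(p_detach)))
        else:
            n_keep = n_frames
        n_keep = max(n_keep, 2) if n_frames >= 2 else n_keep

        paused = _markov_states(rng, n_keep, p_pause, p_resume)
        adv = np.maximum(0.0, rng.normal(motility.speed_mean, motility.speed_jitter_sd, n_keep)) * dt
        adv[0] = 0.0
        adv[paused] = 0.0

        turn = rng.normal(0.0, 1.0, n_keep) * (motility.path_turn_sd * adv / 1000.0)
        turn[0] = 0.0
        headings = heading0 + np.cumsum(turn)
        steps = np.stack([adv * np.cos(headings), adv * np.sin(headings)], axis=1)
        tip = np.array([x0, y0]) + np.cumsum(steps, axis=0)

        # full polyline: straight initial tail of one filament length
        # behind the start, then the tip trajectory
        tail0 = tip[0] - length_nm * np.array([math.cos(heading0), math.sin(heading0)])
        path_xy = np.vstack([tail0, tip])
        seg = np.linalg.norm(np.diff(path_xy, axis=0), axis=1)
        path_s = np.concatenate([[0.0], np.cumsum(seg)])
        tip_s = path_s[1:]
        trail_s = tip_s - length_nm
        path_trailing = np.stack([
            np.interp(trail_s, path_s, path_xy[:, 0]),
            np.interp(trail_s, path_s, path_xy[:, 1]),
        ], axis=1)

        noise_lead = rng.normal(0.0, motility.brownian_end_sd, (n_keep, 2))
        noise_trail = rng.normal(0.0, motility.brownian_end_sd, (n_keep, 2))
        states = np.where(paused, "paused", "moving")
        tracks.append(TruthTrack(
            mt_id=mt_id,
            length_um=length_um,
            times=np.arange(n_keep) * dt,
            leading=tip + noise_lead,
            trailing=path_trailing + noise_trail,
            states=states,
            path_leading=tip,
            path_trailing=path_trailing,
            path_xy=path_xy,
            path_s=path_s,
            tip_s=tip_s,
        ))
    return tracks


def render_stack(truth: list[TruthTrack], imaging: ImagingParams, seed: int,
                 shot_noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render ground-truth tracks into a fluorescence image stack.

    Each filament contributes ``photons_per_um * length_um`` photons per
    frame, deposited by integrating along the body polyline and blurring
    with a Gaussian PSF of ``psf_sigma``.  A constant background is
    added, each pixel is Poisson-sampled (unless ``shot_noise=False``,
    a hook for deterministic tests), counts are clipped to the camera
    bit depth, and a fixed random dead-pixel mask zeroes the same pixels
    in every frame.

    Returns ``(stack, dead_mask)`` with ``stack`` of shape
    ``(n_frames, H, W)`` dtype uint16 and ``dead_mask`` boolean ``(H, W)``.
    """
    H, W = imaging.field_size
    n_frames = max((t.n_frames for t in truth), default=0)
    rng = np.random.default_rng(seed)
    dead_mask = rng.random((H, W)) < imaging.dead_pixel_fraction

    px = imaging.pixel_size
    sigma_px = imaging.psf_sigma / px
    max_count = 2 ** imaging.bit_depth - 1
    stack = np.zeros((n_frames, H, W), dtype=np.uint16)
    # pixel i spans [i*px - px/2, i*px + px/2]; histogram edges accordingly
    y_edges = (np.arange(H + 1) - 0.5) * px
    x_edges = (np.arange(W + 1) - 0.5) * px

    for f in range(n_frames):
        img = np.zeros((H, W), dtype=float)
        for t in truth:
            if f >= t.n_frames:
                continue
            length_nm = t.length_um * 1000.0
            n_samp = max(int(length_nm / (px / 3.0)), 2)
            u = np.linspace(t.tip_s[f] - length_nm, t.tip_s[f], n_samp)
            xs = np.interp(u, t.path_s, t.path_xy[:, 0])
            ys = np.interp(u, t.path_s, t.path_xy[:, 1])
            photons = imaging.photons_per_um * t.length_um
            hist, _, _ = np.histogram2d(ys, xs, bins=(y_edges, x_edges))
            img += hist * (photons / n_samp)
        if sigma_px > 0:
            img = gaussian_filter(img, sigma_px, mode="constant")
        img += imaging.background_mean
        if shot_noise:
            img = rng.poisson(img).astype(float)
        img = np.clip(np.rint(img), 0, max_count)
        frame = img.astype(np.uint16)
        frame[dead_mask] = 0
        stack[f] = frame
    return stack, dead_mask


def make_track_fixture(motility: MotilityParams, n_mt: int, n_frames: int,
                       frame_interval: float, seed: int,
                       pixel_size: float = 133.0) -> pd.DataFrame:
    """Emit ground truth directly in the track-CSV schema, skipping imaging.

    One row per (filament, end, frame); ``area_px`` is the nominal
    segmented area of a ~3-pixel-wide ribbon of the filament's length,
    so the area-based track filter behaves as it would on images.
    """
    imaging = ImagingParams(pixel_size=pixel_size, frame_interval=frame_interval,
                            field_size=(4096, 4096))
    truth = simulate_truth(motility, imaging, n_mt, n_frames, seed)
    parts = []
    for t in truth:
        area = int(round(t.length_um * 1000.0 / pixel_size * 3.0))
        for label, xy in (("leading", t.leading), ("trailing", t.trailing)):
            parts.append(pd.DataFrame({
                "mt_id": t.mt_id,
                "end_label": label,
                "frame": np.arange(t.n_frames),
                "time_s": t.times,
                "x_nm": xy[:, 0],
                "y_nm": xy[:, 1],
                "state": t.states,
                "area_px": area,
            }))
    return pd.concat(parts, ignore_index=True)[TRACK_COLUMNS]
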