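"""Per-frame image operations: dead-pixel repair, segmentation, skeleton
end localization, and the convex-hull/2 filament length estimator.

All operations are deterministic.  Coordinates follow the simulator
convention: continuous nm, origin at the top-left pixel center, x along
columns (rightward), y along rows (downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, distance_transform_edt
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "Frame",
    "SegmentedObject",
    "DegenerateShapeError",
    "UnrecoverableFrameError",
    "repair_dead_pixels",
    "segment",
    "locate_ends",
    "skeletonize",
    "estimate_length",
]


class DegenerateShapeError(ValueError):
    """Skeleton has no endpoints (closed loop); object unusable for tracking."""


class UnrecoverableFrameError(ValueError):
    """Every pixel of the frame is dead."""


@dataclass(frozen=True)
class Frame:
    """One camera frame: nonnegative intensity counts plus geometry/timing."""

    intensity: np.ndarray       # (H, W) nonnegative counts
    pixel_size: float           # nm/px
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity)
        if img.ndim != 2 or min(img.shape) < 16:
            raise ValueError("intensity must be 2-D with H, W >= 16")
        if np.any(img < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class SegmentedObject:
    """One segmented filament candidate in one frame."""

    label: int
    coords: np.ndarray          # (area, 2) int (row, col) pixel coordinates
    area_px: int
    centroid_nm: tuple[float, float]   # (x, y)
    bbox: tuple[int, int, int, int]    # (min_row, min_col, max_row, max_col) exclusive
    frame_index: int = 0
    endpoints_nm: np.ndarray | None = field(default=None)  # (2, 2) [(x, y), (x, y)]
    degenerate: bool = False

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


_NEIGH8 = np.ones((3, 3), dtype=float)
_NEIGH8[1, 1] = 0.0


def repair_dead_pixels(frame: Frame, dead_mask: np.ndarray) -> Frame:
    """Replace each dead pixel by the mean of its live 8-neighbors.

    Pixels whose 8-neighborhood is entirely dead fall back to the value
    of the nearest live pixel.  Live pixels are returned unchanged; the
    operation is idempotent.
    """
    dead = np.asarray(dead_mask, dtype=bool)
    img = np.asarray(frame.intensity, dtype=float)
    if dead.shape != img.shape:
        raise ValueError("dead_mask shape must match frame")
    if not dead.any():
        return frame
    if dead.all():
        raise UnrecoverableFrameError("all pixels are dead")
    live = ~dead
    nsum = convolve(np.where(live, img, 0.0), _NEIGH8, mode="constant")
    ncount = convolve(live.astype(float), _NEIGH8, mode="constant")
    out = img.copy()
    ok = dead & (ncount > 0)
    out[ok] = nsum[ok] / ncount[ok]
    orphan = dead & (ncount == 0)
    if orphan.any():
        _, (ir, ic) = distance_transform_edt(dead, return_indices=True)
        out[orphan] = img[ir[orphan], ic[orphan]]
    return Frame(out, frame.pixel_size, frame.frame_index, frame.time_s)


def segment(frame: Frame, threshold: float | None = None,
            speck_floor: int = 5) -> list[SegmentedObject]:
    """Threshold the frame and extract 8-connected filament candidates.

    Otsu's method supplies the global threshold unless a fixed value is
    given.  Components below ``speck_floor`` pixels are discarded as
    noise specks (this is distinct from the 55-pixel track-level area
    filter applied downstream).
    """
    img = np.asarray(frame.intensity, dtype=float)
    if threshold is None:
        if not np.any(img > img.min()):
            return []
        threshold = threshold_otsu(img)
    binary = img > threshold
    if not binary.any():
        return []
    # a threshold landing inside the background noise floods the frame;
    # filaments never cover a large fraction of the field
    if binary.mean() > 0.2:
        return []
    labels = cc_label(binary, connectivity=2)
    px = frame.pixel_size
    objects = []
    for rp in regionprops(labels):
        if rp.area < speck_floor:
            continue
        cy, cx = rp.centroid
        objects.append(SegmentedObject(
            label=int(rp.label),
            coords=np.asarray(rp.coords),
            area_px=int(rp.area),
            centroid_nm=(cx * px, cy * px),
            bbox=tuple(rp.bbox),
            frame_index=frame.frame_index,
        ))
    return objects


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a binary mask to a 1-px curve."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _skimage_skeletonize(mask)


def _skeleton_neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return convolve(skel.astype(float), _NEIGH8, mode="constant")


def _geodesic_bfs(skel: np.ndarray, start: tuple[int, int]) -> dict[tuple[int, int], int]:
    """Hop distances along the 8-connected skeleton from ``start``."""
    pixels = {tuple(p) for p in np.argwhere(skel)}
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q in pixels and q not in dist:
                        dist[q] = dist[(r, c)] + 1
                        nxt.append(q)
        frontier = nxt
    return dist


def locate_ends(obj: SegmentedObject, frame: Frame) -> np.ndarray:
    """Locate the two filament ends with subpixel accuracy.

    The object's mask is skeletonized; skeleton pixels with exactly one
    skeleton neighbor are endpoint candidates, and the two candidates at
    maximal geodesic (along-skeleton) separation are chosen.  Each is
    refined to subpixel precision by the intensity-weighted centroid of
    its 5x5 neighborhood.  Returns a (2, 2) array of (x, y) nm in
    lexicographic order.

    Raises :class:`DegenerateShapeError` for closed-loop skeletons,
    which carry no endpoints and are excluded from tracking.
    """
    img = np.asarray(frame.intensity, dtype=float)
    skel = skeletonize(obj.mask(img.shape))
    counts = _skeleton_neighbor_counts(skel)
    cand = [tuple(p) for p in np.argwhere(skel & (counts == 1))]
    skel_pts = np.argwhere(skel)
    if len(skel_pts) == 1:
        cand = [tuple(skel_pts[0])] * 2
    elif not cand:
        raise DegenerateShapeError(f"object {obj.label}: closed-loop skeleton")
    elif len(cand) == 1:
        dist = _geodesic_bfs(skel, cand[0])
        far = max(dist, key=dist.get)
        cand = [cand[0], far]
    if len(cand) > 2:
        # double BFS sweep: farthest candidate from an arbitrary start,
        # then farthest from that — the exact diameter on tree skeletons
        cset = set(cand)
        dist = _geodesic_bfs(skel, cand[0])
        a = max((p for p in cand if p in dist), key=dist.get)
        dist = _geodesic_bfs(skel, a)
        b = max((p for p in cset if p in dist), key=dist.get)
        cand = [a, b]

    # thinning retracts tips by a pixel or two: march each endpoint along
    # its local skeleton direction to the mask boundary before refining
    mask = obj.mask(img.shape)
    extended = []
    for r, c in cand[:2]:
        nb = [tuple(p) for p in np.argwhere(skel[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2])]
        nb = [(p[0] + max(r - 1, 0), p[1] + max(c - 1, 0)) for p in nb]
        nb = [p for p in nb if p != (r, c)]
        if nb:
            dr, dc = int(np.sign(r - nb[0][0])), int(np.sign(c - nb[0][1]))
            for _ in range(20):
                for sr, sc in ((dr, dc), (0, dc), (dr, 0)):
                    if sr == sc == 0:
                        continue
                    nr, nc = r + sr, c + sc
                    if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1] and mask[nr, nc]):
                        r, c = nr, nc
                        break
                else:
                    break
        extended.append((r, c))
    cand = extended

    H, W = img.shape
    ends = []
    for r, c in cand[:2]:
        r0, r1 = max(r - 2, 0), min(r + 3, H)
        c0, c1 = max(c - 2, 0), min(c + 3, W)
        win = img[r0:r1, c0:c1]
        total = win.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            ends.append(((cc * win).sum() / total, (rr * win).sum() / total))
        else:
            ends.append((float(c), float(r)))
    ends = np.asarray(sorted(ends)) * frame.pixel_size
    return ends


def estimate_length(mask: np.ndarray, pixel_size: float) -> float:
    """Estimate filament length as (convex-hull perimeter of the
    skeleton) / 2, in micrometres.

    The mask is skeletonized and the hull is computed on skeleton pixel
    centers.  For collinear skeletons the degenerate hull's perimeter is
    twice the maximal pairwise distance, so the estimate reduces to that
    distance.  A single-pixel mask yields 0.0 (too small to measure).
    Slightly underestimates curved filaments: the hull of a concave
    curve is shorter than the curve.
    """
    skel = skeletonize(mask)
    pts = np.argwhere(skel)[:, ::-1].astype(float)  # (col, row) = (x, y) px
    if len(pts) == 1:
        return 0.0
    try:
        perim_px = ConvexHull(pts).area  # in 2-D, .area is the perimeter
    except QhullError:
        perim_px = 2.0 * pdist(pts).max()
    return perim_px / 2.0 * pixel_size / 1000.0
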