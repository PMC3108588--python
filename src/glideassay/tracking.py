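"""Link per-frame detections into microtubule tracks and apply the
track-level retention rules.

Linking is greedy nearest-centroid with a displacement gate — adequate
at gliding-assay densities, where the gate is far smaller than the
typical inter-filament spacing (a documented limitation; no global
assignment, no gap closing).  A track terminates when its filament
approaches the field edge, merges/overlaps with another filament,
disappears, or the stack ends.  Retention follows the standard
gliding-assay rules: at least 100 consecutive tracked frames and a
segmented area of at least 55 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_ops import SegmentedObject

__all__ = ["Track", "link", "filter_tracks", "tracks_from_table", "tracks_to_table"]

MIN_FRAMES_DEFAULT = 100
MIN_AREA_PX_DEFAULT = 55


@dataclass
class Track:
    """A linked time series of one filament with two labeled ends."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    end_a: list[np.ndarray] = field(default_factory=list)   # (x, y) nm
    end_b: list[np.ndarray] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    termination_reason: str = "end_of_stack"

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def median_area_px(self) -> float | None:
        if not self.areas or any(a is None for a in self.areas):
            return None
        return float(np.median(self.areas))

    def end_positions(self, which: str) -> np.ndarray:
        return np.asarray(self.end_a if which == "A" else self.end_b, dtype=float)


def _near_edge(obj: SegmentedObject, edge_margin_px: int, field_size: tuple[int, int]) -> bool:
    r0, c0, r1, c1 = obj.bbox
    H, W = field_size
    return (r0 < edge_margin_px or c0 < edge_margin_px
            or r1 > H - edge_margin_px or c1 > W - edge_margin_px)


def _pair_ends(prev_a: np.ndarray, prev_b: np.ndarray,
               ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep end labels consistent: choose the pairing with the smaller
    total displacement."""
    d_keep = np.linalg.norm(ends[0] - prev_a) + np.linalg.norm(ends[1] - prev_b)
    d_swap = np.linalg.norm(ends[1] - prev_a) + np.linalg.norm(ends[0] - prev_b)
    return (ends[0], ends[1]) if d_keep <= d_swap else (ends[1], ends[0])


def link(detections_by_frame: dict[int, list[SegmentedObject]],
         max_disp_nm: float, edge_margin_px: int = 10,
         field_size: tuple[int, int] = (512, 512)) -> list[Track]:
    """Greedy nearest-centroid linking with termination rules.

    ``detections_by_frame`` maps frame index -> detections (each with
    centroid, area, bbox, and optionally subpixel endpoints).  At each
    step, active tracks claim their nearest detection within the gate
    ``max_disp_nm``; if two tracks claim the same detection the
    filaments have merged and all involved tracks terminate with reason
    ``overlap``.  A detection whose bounding box comes within
    ``edge_margin_px`` of the border terminates its track with reason
    ``edge`` (that frame excluded).  Unmatched, non-edge, non-degenerate
    detections start new tracks.
    """
    frames = sorted(detections_by_frame)
    if frames != sorted(set(frames)):
        raise ValueError("non-monotone frame indices")
    tracks: list[Track] = []
    active: dict[int, Track] = {}
    next_id = 0

    def _start(obj: SegmentedObject, f: int) -> None:
        nonlocal next_id
        if obj.degenerate or obj.endpoints_nm is None:
            return
        if _near_edge(obj, edge_margin_px, field_size):
            return
        tr = Track(track_id=next_id)
        _append(tr, obj, f)
        active[next_id] = tr
        tracks.append(tr)
        next_id += 1

    def _append(tr: Track, obj: SegmentedObject, f: int) -> None:
        ends = np.asarray(obj.endpoints_nm, dtype=float)
        if tr.frames:
            a, b = _pair_ends(tr.end_a[-1], tr.end_b[-1], ends)
        else:
            a, b = ends[0], ends[1]
        tr.frames.append(f)
        tr.end_a.append(np.asarray(a))
        tr.end_b.append(np.asarray(b))
        tr.centroids.append(np.asarray(obj.centroid_nm, dtype=float))
        tr.areas.append(obj.area_px)

    prev_frame = None
    for f in frames:
        dets = [d for d in detections_by_frame[f] if not d.degenerate]
        if prev_frame is not None and f != prev_frame + 1 and active:
            # gap in the frame grid: nothing can be linked across it
            for tr in active.values():
                tr.termination_reason = "disappeared"
            active.clear()
        claims: dict[int, list[int]] = {}
        assigned: dict[int, int] = {}
        if active and dets:
            cents = np.asarray([d.centroid_nm for d in dets], dtype=float)
            for tid, tr in active.items():
                d2 = np.linalg.norm(cents - tr.centroids[-1], axis=1)
                j = int(np.argmin(d2))
                if d2[j] <= max_disp_nm:
                    claims.setdefault(j, []).append(tid)
            for j, tids in claims.items():
                if len(tids) > 1:
                    for tid in tids:  # merged component: overlap
                        active[tid].termination_reason = "overlap"
                        del active[tid]
                else:
                    assigned[tids[0]] = j
        for tid in list(active):
            if tid not in assigned:
                active[tid].termination_reason = "disappeared"
                del active[tid]
        used = set()
        for tid, j in assigned.items():
            obj = dets[j]
            used.add(j)
            tr = active[tid]
            if _near_edge(obj, edge_margin_px, field_size):
                tr.termination_reason = "edge"
                del active[tid]
            elif obj.endpoints_nm is None:
                tr.termination_reason = "disappeared"
                del active[tid]
            else:
                _append(tr, obj, f)
        for j, obj in enumerate(dets):
            if j not in used:
                _start(obj, f)
        prev_frame = f
    for tr in active.values():
        tr.termination_reason = "end_of_stack"
    return tracks


def filter_tracks(tracks: list[Track], min_frames: int = MIN_FRAMES_DEFAULT,
                  min_area_px: int = MIN_AREA_PX_DEFAULT) -> tuple[list[Track], dict[str, int]]:
    """Retain tracks with >= ``min_frames`` consecutive frames and a
    median segmented area >= ``min_area_px``.

    Tracks whose detections carry no area (pre-extracted tables without
    the optional column) skip the area test.  Returns the retained
    tracks (input order preserved) and a report of discard counts.
    """
    retained: list[Track] = []
    report = {"input": len(tracks), "retained": 0,
              "discarded_min_frames": 0, "discarded_min_area": 0}
    for tr in tracks:
        if tr.n_frames < min_frames:
            report["discarded_min_frames"] += 1
            continue
        med = tr.median_area_px
        if med is not None and med < min_area_px:
            report["discarded_min_area"] += 1
            continue
        retained.append(tr)
    report["retained"] = len(retained)
    return retained, report


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    """Build Track objects from a track table (simulator/tracker schema).

    The leading end maps to end A, the trailing end to end B.
    """
    required = {"mt_id", "end_label", "frame", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for mt_id, g in df.groupby("mt_id", sort=True):
        lead = g[g.end_label == "leading"].sort_values("frame")
        trail = g[g.end_label == "trailing"].sort_values("frame")
        tr = Track(track_id=int(mt_id))
        tr.frames = lead.frame.astype(int).tolist()
        tr.end_a = list(lead[["x_nm", "y_nm"]].to_numpy(dtype=float))
        tr.end_b = list(trail[["x_nm", "y_nm"]].to_numpy(dtype=float))
        mids = (lead[["x_nm", "y_nm"]].to_numpy(dtype=float)
                + trail[["x_nm", "y_nm"]].to_numpy(dtype=float)) / 2.0
        tr.centroids = list(mids)
        if "area_px" in g.columns and not g.area_px.isna().any():
            tr.areas = lead.area_px.astype(int).tolist()
        else:
            tr.areas = [None] * len(tr.frames)
        tracks.append(tr)
    return tracks


def tracks_to_table(tracks: list[Track], frame_interval: float) -> pd.DataFrame:
    """Serialize tracks to the shared track-table schema (plus
    termination_reason)."""
    parts = []
    for tr in tracks:
        frames = np.asarray(tr.frames, dtype=int)
        for label, arr in (("leading", tr.end_positions("A")),
                           ("trailing", tr.end_positions("B"))):
            parts.append(pd.DataFrame({
                "mt_id": tr.track_id,
                "end_label": label,
                "frame": frames,
                "time_s": frames * frame_interval,
                "x_nm": arr[:, 0],
                "y_nm": arr[:, 1],
                "state": "",
                "area_px": tr.areas,
                "termination_reason": tr.termination_reason,
            }))
    if not parts:
        return pd.DataFrame(columns=["mt_id", "end_label", "frame", "time_s",
                                     "x_nm", "y_nm", "state", "area_px",
                                     "termination_reason"])
    return pd.concat(parts, ignore_index=True)
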