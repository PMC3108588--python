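"""File formats: multi-page 16-bit TIFF stacks with a JSON metadata
sidecar, track/detection/estimate CSV tables, and YAML pipeline
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .sim_assay import TRACK_COLUMNS, ImagingParams, MotilityParams
from .speed_stats import AssayAggregate, RoiSpeedEstimate, SpeedConfig

__all__ = [
    "PipelineConfig", "SchemaError",
    "write_stack", "read_stack",
    "write_tracks", "read_tracks",
    "write_estimates", "read_estimates", "write_aggregates",
]


class SchemaError(ValueError):
    """A CSV is missing required columns."""


@dataclass
class PipelineConfig:
    """Resolved configuration for a full simulate/analyze run.

    Every defaulted parameter is materialized on construction, so the
    config written next to each run's outputs is complete and the run
    reproducible from it plus the seed.
    """

    motility: MotilityParams = field(default_factory=MotilityParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    speed: SpeedConfig = field(default_factory=SpeedConfig)
    seed: int = 0
    n_mt: int = 10
    n_frames: int = 600
    threshold: float | None = None
    speck_floor: int = 5
    edge_margin_px: int = 10
    min_frames: int = 100
    min_area_px: int = 55
    out_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("motility", MotilityParams), ("imaging", ImagingParams),
                         ("speed", SpeedConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tup_key in ("length_range_um", "field_size"):
                    if tup_key in sub and isinstance(sub[tup_key], list):
                        sub[tup_key] = tuple(sub[tup_key])
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)


def write_stack(path: str | Path, stack: np.ndarray, imaging: ImagingParams,
                seed: int | None = None, dead_mask: np.ndarray | None = None) -> None:
    """Write a (T, H, W) uint16 stack as multi-page TIFF plus a JSON
    sidecar recording pixel size, frame interval, and seed."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))
    meta = {"pixel_size_nm": imaging.pixel_size,
            "frame_interval_s": imaging.frame_interval,
            "bit_depth": imaging.bit_depth,
            "n_frames": int(stack.shape[0]) if stack.ndim == 3 else 1,
            "seed": seed}
    if dead_mask is not None:
        meta["dead_pixels_rc"] = np.argwhere(dead_mask).tolist()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict, np.ndarray | None]:
    """Read a TIFF stack and its sidecar; returns (stack, meta, dead_mask)."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    dead_mask = None
    if meta.get("dead_pixels_rc"):
        dead_mask = np.zeros(stack.shape[1:], dtype=bool)
        rc = np.asarray(meta["dead_pixels_rc"], dtype=int)
        dead_mask[rc[:, 0], rc[:, 1]] = True
    return stack, meta, dead_mask


def write_tracks(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = [c for c in TRACK_COLUMNS if c not in ("state", "area_px")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"track CSV {path} missing column(s): {missing}")
    return df


ESTIMATE_COLUMNS = ["assay_id", "roi_id", "assay_time_s", "mode_nm_s", "n_tracks", "n_samples"]


def write_estimates(path: str | Path, estimates: list[RoiSpeedEstimate]) -> None:
    rows = [{"assay_id": e.assay_id, "roi_id": e.roi_id,
             "assay_time_s": e.assay_time_s,
             "mode_nm_s": e.mode_nm_s if e.mode_nm_s is not None else np.nan,
             "n_tracks": e.n_tracks, "n_samples": e.n_samples}
            for e in estimates]
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(path, index=False)


def read_estimates(path: str | Path) -> list[RoiSpeedEstimate]:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"estimate CSV {path} missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        mode = None if pd.isna(row.mode_nm_s) else float(row.mode_nm_s)
        out.append(RoiSpeedEstimate(int(row.roi_id), int(row.assay_id),
                                    float(row.assay_time_s), mode,
                                    int(row.n_tracks), int(row.n_samples)))
    return out


def write_aggregates(path: str | Path, aggregates: list[AssayAggregate]) -> None:
    rows = [{"assay_time_s": a.assay_time_s, "mean_nm_s": a.mean_nm_s,
             "sem_nm_s": a.sem_nm_s if a.sem_nm_s is not None else np.nan,
             "n_assays": a.n_assays} for a in aggregates]
    pd.DataFrame(rows, columns=["assay_time_s", "mean_nm_s", "sem_nm_s", "n_assays"]
                 ).to_csv(path, index=False)
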