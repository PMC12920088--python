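"""Tabular and map I/O: track-table CSV, float32 TIFF maps with JSON
sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import GridSpec
from .tracking import TrackSet

__all__ = ["write_track_table", "read_track_table", "write_map", "read_map"]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "z_um",
                 "vx_mm_s", "vz_mm_s", "corr", "backscatter"]


def write_track_table(tracks: TrackSet | pd.DataFrame, path: str | Path) -> None:
    """Write tracks (or a detection table with empty track_id) as CSV."""
    df = tracks.to_frame() if isinstance(tracks, TrackSet) else tracks.copy()
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[TRACK_COLUMNS].to_csv(path, index=False)


def read_track_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map(arr: np.ndarray, grid: GridSpec, path: str | Path,
              extra_meta: dict | None = None) -> None:
    """Single-page float32 TIFF plus a JSON sidecar carrying the GridSpec."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    meta = dataclasses.asdict(grid)
    meta["origin"] = list(meta["origin"])
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_map(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta
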