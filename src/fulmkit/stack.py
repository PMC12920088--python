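"""FrameStack container and HDF5 / multi-page TIFF I/O.

A :class:`FrameStack` holds a 2D+time ultrafast movie as an
``(n_z, n_x, n_frames)`` array (real amplitude or complex IQ) together with
its :class:`~fulmkit.config.GridSpec` and frame rate.  HDF5 files store the
movie under ``/frames`` with metadata in root attributes; multi-page TIFF
stores one page per frame with a JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .config import GridSpec

__all__ = ["FrameStack", "save_stack", "load_stack"]

_REQUIRED_META = (
    "native_pitch_x",
    "native_pitch_z",
    "fine_factor",
    "interp_factor",
    "frame_rate_hz",
)


@dataclass
class FrameStack:
    """2D+time amplitude movie with grid and frame-rate metadata."""

    values: np.ndarray  # (n_z, n_x, n_frames), real or complex
    grid: GridSpec
    frame_rate_hz: float
    provenance: str = "raw"  # raw | filtered | interpolated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_z, n_x, n_frames)")
        nz, nx, _ = self.values.shape
        if (nz, nx) != (self.grid.n_z_native, self.grid.n_x_native):
            raise ValueError(
                f"frame shape {(nz, nx)} does not match grid "
                f"{(self.grid.n_z_native, self.grid.n_x_native)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _meta_dict(stack: FrameStack) -> dict:
    meta = dataclasses.asdict(stack.grid)
    meta["origin"] = list(meta["origin"])
    meta["frame_rate_hz"] = stack.frame_rate_hz
    meta["provenance"] = stack.provenance
    return meta


def _stack_from_meta(values: np.ndarray, meta: dict, path) -> FrameStack:
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"{path}: missing required metadata field '{key}'")
    grid_fields = {f.name for f in dataclasses.fields(GridSpec)}
    grid_kwargs = {k: v for k, v in meta.items() if k in grid_fields}
    grid_kwargs["origin"] = tuple(grid_kwargs.get("origin", (0.0, 0.0)))
    grid = GridSpec(**grid_kwargs)
    return FrameStack(
        values=values,
        grid=grid,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        provenance=str(meta.get("provenance", "raw")),
    )


def save_stack(stack: FrameStack, path: str | Path, fmt: str | None = None) -> None:
    """Save a FrameStack as HDF5 (``.h5``) or multi-page TIFF + JSON sidecar."""
    path = Path(path)
    fmt = fmt or ("tiff" if path.suffix.lower() in (".tif", ".tiff") else "hdf5")
    meta = _meta_dict(stack)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=stack.values)
            f.attrs["meta"] = json.dumps(meta)
    elif fmt == "tiff":
        if np.iscomplexobj(stack.values):
            # TIFF has no complex sample format; store magnitude and phase pages
            # interleaved would be lossy bookkeeping — require HDF5 instead.
            raise ValueError("complex stacks must be saved as HDF5")
        # pages are frames: (n_frames, n_z, n_x)
        tifffile.imwrite(path, np.moveaxis(stack.values, 2, 0))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_stack(path: str | Path, fmt: str | None = None) -> FrameStack:
    """Load a FrameStack saved by :func:`save_stack`.

    Raises ``KeyError`` naming the first absent metadata field, and
    ``FileNotFoundError``/``OSError`` for missing or truncated files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("tiff" if path.suffix.lower() in (".tif", ".tiff") else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            values = f["frames"][()]
            meta = json.loads(f.attrs.get("meta", "{}"))
    elif fmt == "tiff":
        pages = tifffile.imread(path)
        if pages.ndim == 2:  # single-page stack
            pages = pages[None]
        values = np.moveaxis(pages, 0, 2)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise KeyError(
                f"{path}: metadata sidecar {sidecar.name} not found "
                "(missing required metadata field 'native_pitch_x')"
            )
        meta = json.loads(sidecar.read_text())
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _stack_from_meta(values, meta, path)
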