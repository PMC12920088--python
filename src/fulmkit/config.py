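"""Acquisition geometry, protocol configuration and shared timing conventions.

Conventions used throughout the package:

* Positions are stored continuously in micrometres (µm).  The ``x`` axis runs
  along the transducer line; ``z = 0`` at the cortical surface and increases
  with depth, so descending arteriolar flow has ``v_z > 0``.
* Pixels are 0-indexed and cover the half-open interval
  ``[k * pitch, (k + 1) * pitch)``; a continuous position ``p`` rasterizes to
  ``floor(p / pitch)``.
* The *native* grid is the beamformed compound-image grid (lateral pitch =
  probe element pitch, axial pitch = wavelength λ by default).  ULM maps live
  on the *fine* grid (native pitch / ``fine_factor``); localization runs on an
  intermediate ×``interp_factor`` compute grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GridSpec",
    "AcquisitionConfig",
    "StimulusProtocol",
    "derive_timebase",
    "load_config",
    "save_config",
    "INJECTED_VOLUME_ML",
    "MOUSE_BLOOD_VOLUME_ML",
]

#: Microbubble bolus volume (ml) delivered per acquisition and the total
#: blood volume of a 25 g mouse — the protocol's injected-volume bound.
INJECTED_VOLUME_ML = 0.4
MOUSE_BLOOD_VOLUME_ML = 1.8


def _wavelength_um(sound_speed_m_s: float, center_frequency_hz: float) -> float:
    return sound_speed_m_s / center_frequency_hz * 1e6


@dataclass(frozen=True)
class AcquisitionConfig:
    """Ultrafast compound acquisition parameters.

    Defaults are the 15 MHz transcranial mouse protocol: 11 tilted plane
    waves fired at a 5.5 kHz PRF give compound frames at 500 Hz, processed
    in blocks of 200 frames with SVD clutter cuts of 20 (ULM) and 60
    (power Doppler).
    """

    prf_hz: float = 5500.0
    n_angles: int = 11
    block_size: int = 200
    svd_cut_ulm: int = 20
    svd_cut_fus: int = 60
    center_frequency_hz: float = 15e6
    sound_speed_m_s: float = 1540.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.prf_hz <= 0 or self.n_angles <= 0:
            raise ValueError("prf_hz and n_angles must be positive")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        for cut in (self.svd_cut_ulm, self.svd_cut_fus):
            if not 0 <= cut < self.block_size:
                raise ValueError(
                    f"SVD cut {cut} must lie in [0, block_size={self.block_size})"
                )

    @property
    def frame_rate_hz(self) -> float:
        """Compound frame rate = PRF / number of angles (500 Hz at defaults)."""
        return self.prf_hz / self.n_angles

    @property
    def block_rate_hz(self) -> float:
        """Rate of complete blocks (power-Doppler frame rate), 2.5 Hz at defaults."""
        return self.frame_rate_hz / self.block_size

    @property
    def wavelength_um(self) -> float:
        return _wavelength_um(self.sound_speed_m_s, self.center_frequency_hz)


@dataclass(frozen=True)
class GridSpec:
    """Native/fine/compute grid geometry.

    ``native_pitch_z`` defaults to the wavelength λ (≈102.67 µm at 15 MHz in
    1540 m/s medium), so the fine axial pitch is λ/16 ≈ 6.42 µm (printed as
    6.5 µm in display contexts); the fine lateral pitch is 110/16 = 6.875 µm.
    """

    n_x_native: int
    n_z_native: int
    native_pitch_x: float = 110.0
    native_pitch_z: float = field(
        default_factory=lambda: _wavelength_um(1540.0, 15e6)
    )
    fine_factor: int = 16
    interp_factor: int = 6
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.native_pitch_x <= 0 or self.native_pitch_z <= 0:
            raise ValueError("pitches must be positive")
        if self.fine_factor < 1 or self.interp_factor < 1:
            raise ValueError("grid factors must be >= 1")
        if self.n_x_native < 1 or self.n_z_native < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def fine_pitch_x(self) -> float:
        return self.native_pitch_x / self.fine_factor

    @property
    def fine_pitch_z(self) -> float:
        return self.native_pitch_z / self.fine_factor

    @property
    def n_x_fine(self) -> int:
        return self.n_x_native * self.fine_factor

    @property
    def n_z_fine(self) -> int:
        return self.n_z_native * self.fine_factor

    @property
    def extent_x_um(self) -> float:
        return self.n_x_native * self.native_pitch_x

    @property
    def extent_z_um(self) -> float:
        return self.n_z_native * self.native_pitch_z

    def fine_pixel(self, x_um: np.ndarray, z_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rasterize continuous positions onto the fine grid (col, row)."""
        col = np.floor(np.asarray(x_um) / self.fine_pitch_x).astype(int)
        row = np.floor(np.asarray(z_um) / self.fine_pitch_z).astype(int)
        return col, row


@dataclass(frozen=True)
class StimulusProtocol:
    """Block-design whisker-stimulation protocol.

    The fULM protocol repeats 30 s rest / 30 s stimulation / 10 s rest for
    25 patterns (70 s per pattern, ~30 min total); whiskers are brushed at
    2 Hz.  fUS-only variants (50/10 ×10 or 30/30 ×10) use the ``variant``
    tag.
    """

    rest_s: float = 30.0
    stim_s: float = 30.0
    post_s: float = 10.0
    n_patterns: int = 25
    stim_freq_hz: float = 2.0
    variant: str = "fulm-30/30/10x25"

    def __post_init__(self) -> None:
        if min(self.rest_s, self.stim_s, self.post_s) < 0 or self.stim_s <= 0:
            raise ValueError("window durations must be non-negative, stim_s > 0")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")

    @property
    def pattern_duration_s(self) -> float:
        return self.rest_s + self.stim_s + self.post_s

    @property
    def total_duration_s(self) -> float:
        return self.pattern_duration_s * self.n_patterns

    def label(self, t_in_pattern: np.ndarray) -> np.ndarray:
        """Window label for pattern-relative times in [0, pattern_duration)."""
        t = np.asarray(t_in_pattern, dtype=float)
        out = np.where(
            t < self.rest_s,
            "baseline",
            np.where(t < self.rest_s + self.stim_s, "stimulation", "post"),
        )
        return out

    def n_windows_per_pattern(self, window_s: float = 2.0) -> int:
        n = self.pattern_duration_s / window_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window {window_s} s does not divide pattern duration "
                f"{self.pattern_duration_s} s"
            )
        return int(round(n))

    def n_windows_total(self, window_s: float = 2.0) -> int:
        return self.n_windows_per_pattern(window_s) * self.n_patterns


def derive_timebase(
    acq: AcquisitionConfig,
    protocol: StimulusProtocol,
    window_s: float = 2.0,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Per-frame timing table tying frames to the stimulation protocol.

    Returns a DataFrame with one row per frame: absolute time ``t_s``,
    ``pattern`` index, pattern-relative time ``t_in_pattern``, window
    ``label`` (baseline / stimulation / post) and the index of the
    ``window_s``-long dynamic accumulation window the frame falls into.
    """
    protocol.n_windows_per_pattern(window_s)  # validates divisibility
    rate = acq.frame_rate_hz
    if n_frames is None:
        n_frames = int(round(protocol.total_duration_s * rate))
    frames = np.arange(n_frames)
    t_s = frames / rate
    pattern = np.floor(t_s / protocol.pattern_duration_s).astype(int)
    t_in = t_s - pattern * protocol.pattern_duration_s
    return pd.DataFrame(
        {
            "frame": frames,
            "t_s": t_s,
            "pattern": pattern,
            "t_in_pattern": t_in,
            "label": protocol.label(t_in),
            "window": np.floor(t_s / window_s).astype(int),
        }
    )


# -- YAML/JSON config round-trip ---------------------------------------------

_CONFIG_TYPES = {
    "grid": GridSpec,
    "acquisition": AcquisitionConfig,
    "protocol": StimulusProtocol,
}


def save_config(path: str | Path, **sections) -> None:
    """Write config dataclasses (grid=, acquisition=, protocol=) to YAML."""
    payload = {}
    for key, obj in sections.items():
        payload[key] = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) config; known sections become dataclasses."""
    text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError:
        payload = json.loads(text)
    out = {}
    for key, value in (payload or {}).items():
        cls = _CONFIG_TYPES.get(key)
        if cls is not None and isinstance(value, dict):
            if "origin" in value and isinstance(value["origin"], list):
                value = {**value, "origin": tuple(value["origin"])}
            out[key] = cls(**value)
        else:
            out[key] = value
    return out
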