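"""Microbubble transit simulation along a synthetic vascular tree.

Bubble entries into each segment follow an (inhomogeneous) Poisson process;
during stimulation the entry rate of activated segments rises by
``activation_gain`` after ``activation_delay_s``, with a linear ramp and an
optional initial overshoot — the two-phase shape of the functional
hyperaemic response.  Each bubble advances along the segment centerline at
the segment speed with a constant lateral offset drawn uniformly within the
tube radius (resampled per bubble, keeping individual tracks smooth), and
carries a log-normal echo amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import AcquisitionConfig, StimulusProtocol
from .tree import PhenotypeParams, VesselSegmentSpec

__all__ = ["GroundTruth", "simulate_tracks", "stimulation_multiplier"]


@dataclass
class GroundTruth:
    """Ground-truth record of one simulated acquisition."""

    tracks: pd.DataFrame  # per (track, frame): positions, velocities, amplitude
    flux: pd.DataFrame  # per-segment realized entry counts per 1-s bin
    tree: list[VesselSegmentSpec]
    seed: int
    frame_rate_hz: float
    duration_s: float

    def positions_in_frame(self, frame: int) -> pd.DataFrame:
        return self.tracks[self.tracks["frame"] == frame]


def stimulation_multiplier(
    t_in_pattern: np.ndarray,
    protocol: StimulusProtocol,
    phenotype: PhenotypeParams,
) -> np.ndarray:
    """Flux multiplier m(t) within one pattern for an activated segment.

    1 at rest; ramps linearly to ``1 + gain`` over ``activation_rise_s``
    starting ``activation_delay_s`` after stimulation onset; optionally
    overshoots to ``1 + gain + overshoot_gain`` during the ramp's plateau
    onset before settling; returns to 1 after stimulation end.
    """
    t = np.asarray(t_in_pattern, dtype=float)
    onset = protocol.rest_s + phenotype.activation_delay_s
    end = protocol.rest_s + protocol.stim_s
    rise = max(phenotype.activation_rise_s, 1e-9)
    ramp = np.clip((t - onset) / rise, 0.0, 1.0)
    ramp = np.where((t >= end) | (t < onset), 0.0, ramp)
    m = 1.0 + phenotype.activation_gain * ramp
    if phenotype.activation_overshoot and phenotype.overshoot_gain > 0:
        # transient extra gain over ~2 rise-times after the ramp completes
        peak_t = onset + rise
        over = np.exp(-np.clip(t - peak_t, 0, None) / (2.0 * rise))
        over = np.where((t >= peak_t) & (t < end), over, 0.0)
        m = m + phenotype.overshoot_gain * over
    return m


def _arc_geometry(centerline: np.ndarray):
    steps = np.diff(centerline, axis=0)
    seg_len = np.hypot(steps[:, 0], steps[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    with np.errstate(invalid="ignore", divide="ignore"):
        tangents = steps / seg_len[:, None]
    tangents = np.nan_to_num(tangents)
    return s, tangents


def _position_at(centerline, s_vertices, tangents, s):
    """Point and tangent at arc length(s) s along the polyline."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    idx = np.clip(np.searchsorted(s_vertices, s, side="right") - 1, 0,
                  len(tangents) - 1)
    base = centerline[idx]
    tang = tangents[idx]
    pos = base + (s - s_vertices[idx])[:, None] * tang
    return pos, tang


def simulate_tracks(
    tree: list[VesselSegmentSpec],
    protocol: StimulusProtocol,
    phenotype: PhenotypeParams,
    acq: AcquisitionConfig,
    seed: int = 0,
    duration_s: float | None = None,
    amplitude_sigma: float = 0.3,
) -> GroundTruth:
    """Simulate ground-truth microbubble tracks for one acquisition.

    ``duration_s`` defaults to the full protocol duration; shorter values
    truncate the acquisition (the protocol timing is unchanged, so partial
    scenes still know where stimulation windows fall).
    """
    rate_hz = acq.frame_rate_hz
    if duration_s is None:
        duration_s = acq.duration_s or protocol.total_duration_s
    n_frames = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    rng = np.random.default_rng(seed)

    frame_t = np.arange(n_frames) * dt
    t_in_pattern = np.mod(frame_t, protocol.pattern_duration_s)

    rows = []
    flux_rows = []
    track_id = 0
    for seg in tree:
        if seg.bubble_rate <= 0 or seg.mean_speed <= 0:
            continue
        s_vertices, tangents = _arc_geometry(seg.centerline)
        length = s_vertices[-1]
        mult = (stimulation_multiplier(t_in_pattern, protocol, phenotype)
                if seg.activated else np.ones(n_frames))
        lam = seg.bubble_rate * mult * dt
        entries = rng.poisson(lam)
        entry_frames = np.repeat(np.arange(n_frames), entries)
        # realized flux per 1-s bin
        sec = np.arange(int(np.ceil(duration_s)))
        counts = np.bincount((entry_frames * dt).astype(int),
                             minlength=len(sec))[: len(sec)]
        flux_rows.append(pd.DataFrame({
            "segment_id": seg.id, "t_s": sec, "entries": counts,
            "activated": seg.activated,
        }))
        speed_um_s = seg.mean_speed * 1e3  # mm/s -> µm/s
        n_steps_max = int(np.floor(length / (speed_um_s * dt)))
        for f0 in entry_frames:
            offset = rng.uniform(-0.5, 0.5) * (seg.diameter - 1e-6)
            amp = float(rng.lognormal(mean=0.0, sigma=amplitude_sigma))
            n_steps = min(n_steps_max, n_frames - 1 - f0)
            if n_steps < 0:
                continue
            k = np.arange(n_steps + 1)
            s = k * speed_um_s * dt
            pos, tang = _position_at(seg.centerline, s_vertices, tangents, s)
            normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
            pos = pos + offset * normal
            v = tang * seg.mean_speed  # mm/s components along flow
            n = n_steps + 1
            rows.append((
                np.full(n, track_id), f0 + k, pos, v,
                np.full(n, amp), np.full(n, seg.id), seg.vessel_class,
            ))
            track_id += 1

    if rows:
        tid = np.concatenate([r[0] for r in rows])
        frm = np.concatenate([r[1] for r in rows])
        pos = np.concatenate([r[2] for r in rows], axis=0)
        vel = np.concatenate([r[3] for r in rows], axis=0)
        amp = np.concatenate([r[4] for r in rows])
        sid = np.concatenate([r[5] for r in rows])
        cls = np.concatenate([np.full(len(r[0]), r[6], dtype=object)
                              for r in rows])
        tracks = pd.DataFrame({
            "track_id": tid.astype(int),
            "frame": frm.astype(int),
            "t_s": frm * dt,
            "x_um": pos[:, 0],
            "z_um": pos[:, 1],
            "vx_mm_s": vel[:, 0],
            "vz_mm_s": vel[:, 1],
            "speed_mm_s": np.hypot(vel[:, 0], vel[:, 1]),
            "amplitude": amp,
            "segment_id": sid.astype(int),
            "vessel_class": pd.Categorical(cls),
        })
    else:
        tracks = pd.DataFrame(columns=[
            "track_id", "frame", "t_s", "x_um", "z_um", "vx_mm_s", "vz_mm_s",
            "speed_mm_s", "amplitude", "segment_id", "vessel_class"])
    flux = (pd.concat(flux_rows, ignore_index=True) if flux_rows
            else pd.DataFrame(columns=["segment_id", "t_s", "entries", "activated"]))
    return GroundTruth(tracks=tracks, flux=flux, tree=tree, seed=seed,
                       frame_rate_hz=rate_hz, duration_s=duration_s)
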