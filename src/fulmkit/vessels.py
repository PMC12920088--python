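"""Vessel segmentation and morpho-haemodynamic quantification.

Vessels are segmented by a Frangi vesselness filter applied to
``sqrt(mb_flow) × speed / speed_normalizer`` (normalizer = 99th percentile
of the speed map), binarized by Otsu's threshold, and filtered by
major-axis length; each component is classified arteriole (downward flow,
presence-weighted mean v_z > 0) or venule (upward).  Per-vessel outputs:
depth profiles of flow and speed along lines orthogonal to the centerline,
diameters as the full width at half maximum of the orthogonal backscatter
profile, tortuosity as the circular standard deviation of the
velocity-vector direction angles (variant: standard deviation of scalar
products of consecutive unit vectors), and the roundness metric
``4·area / (π·major_axis²)`` used for cell-soma morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import circstd
from skimage.filters import apply_hysteresis_threshold, frangi, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .config import GridSpec
from .maps import ULMMaps
from .tracking import TrackSet, compute_velocities

__all__ = [
    "VesselSegment",
    "DepthProfile",
    "TortuosityResult",
    "DiameterResult",
    "segment_vessels",
    "depth_profile",
    "measure_diameter",
    "tortuosity",
    "roundness",
]


@dataclass
class VesselSegment:
    """One segmented vessel on the fine grid."""

    mask: np.ndarray  # boolean, fine grid
    centerline: np.ndarray  # (n, 2) of (x, z) µm, ordered by depth
    vessel_class: str  # arteriole | venule
    length_um: float
    depth_extent_um: tuple[float, float]
    mean_vz: float = 0.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)


@dataclass
class DepthProfile:
    depths_um: np.ndarray
    mb_flow: np.ndarray  # integral across the orthogonal line
    speed: np.ndarray  # peak across the orthogonal line


@dataclass
class TortuosityResult:
    vessel_id: int
    statistic: float  # radians (angle mode) or dimensionless (dot mode)
    mode: str
    n_vectors: int
    n_tracks: int


@dataclass
class DiameterResult:
    value_um: float | None
    flagged: bool
    reason: str = ""


def segment_vessels(maps: ULMMaps, min_major_axis_um: float = 500.0,
                    frangi_sigmas=range(1, 9),
                    low_fraction: float = 0.08) -> list[VesselSegment]:
    """Segment vessels from co-registered ULM maps.

    The vesselness map is binarized by hysteresis: seeds above Otsu's
    threshold grow down to ``low_fraction`` of it, which keeps slow (dim)
    capillary-side continuations attached to their bright parent
    arterioles; a light morphological closing bridges single-pixel gaps.
    Returns one VesselSegment per connected component whose major axis is
    at least ``min_major_axis_um``; empty input yields an empty list.
    """
    flow = maps.mb_flow
    if not np.any(flow > 0):
        return []
    speed = maps.speed
    norm = np.percentile(speed[speed > 0], 99) if np.any(speed > 0) else 1.0
    vin = np.sqrt(flow) * (speed / max(norm, 1e-12))
    vness = frangi(vin, sigmas=list(frangi_sigmas), black_ridges=False)
    if not np.any(vness > 0):
        return []
    thr = threshold_otsu(vness)
    binary = apply_hysteresis_threshold(vness, low_fraction * thr, thr)
    binary = closing(binary, disk(2))
    lab = label(binary, connectivity=2)
    grid = maps.grid
    px, pz = grid.fine_pitch_x, grid.fine_pitch_z
    pitch = 0.5 * (px + pz)
    segments = []
    for rp in regionprops(lab):
        if rp.axis_major_length * pitch < min_major_axis_um:
            continue
        mask = lab == rp.label
        w = flow * mask
        total = w.sum()
        if total <= 0:
            continue
        mean_vz = float((maps.vz * w).sum() / total)
        rows = np.flatnonzero(mask.any(axis=1))
        center = []
        for r in rows:
            wr = w[r]
            if wr.sum() <= 0:
                cols = np.flatnonzero(mask[r])
                cx = cols.mean()
            else:
                cx = (np.arange(mask.shape[1]) * wr).sum() / wr.sum()
            center.append(((cx + 0.5) * px, (r + 0.5) * pz))
        center = np.asarray(center)
        steps = np.diff(center, axis=0)
        length = float(np.sum(np.hypot(steps[:, 0], steps[:, 1]))) if len(center) > 1 else 0.0
        segments.append(VesselSegment(
            mask=mask,
            centerline=center,
            vessel_class="arteriole" if mean_vz > 0 else "venule",
            length_um=length,
            depth_extent_um=(float(center[:, 1].min()), float(center[:, 1].max())),
            mean_vz=mean_vz,
        ))
    segments.sort(key=lambda s: s.centerline[0, 0])
    return segments


def _centerline_at_depth(segment: VesselSegment, depth_um: float):
    """Centerline point and unit tangent at a given depth (interpolated)."""
    c = segment.centerline
    z = c[:, 1]
    x = np.interp(depth_um, z, c[:, 0])
    # tangent from neighbouring samples
    i = np.clip(np.searchsorted(z, depth_um), 1, len(z) - 1)
    d = c[i] - c[i - 1]
    n = np.linalg.norm(d)
    tang = d / n if n > 0 else np.array([0.0, 1.0])
    return np.array([x, depth_um]), tang


def _orthogonal_samples(maps_arr: np.ndarray, grid: GridSpec, point, tangent,
                        half_width_um: float, step_um: float):
    normal = np.array([-tangent[1], tangent[0]])
    offsets = np.arange(-half_width_um, half_width_um + step_um / 2, step_um)
    pts = point[None, :] + offsets[:, None] * normal[None, :]
    cols = pts[:, 0] / grid.fine_pitch_x - 0.5
    rows = pts[:, 1] / grid.fine_pitch_z - 0.5
    vals = map_coordinates(maps_arr, [rows, cols], order=1, mode="constant")
    return offsets, vals


def depth_profile(maps: ULMMaps, segment: VesselSegment,
                  depth_step_um: float = 50.0,
                  half_width_um: float = 60.0) -> DepthProfile:
    """Flow/speed profiles along the vessel: at each depth a line orthogonal
    to the local centerline samples the maps; speed takes the line's peak,
    flow its integral."""
    z0, z1 = segment.depth_extent_um
    if z1 - z0 <= depth_step_um:
        raise ValueError("centerline spans fewer than two depth steps")
    depths = np.arange(z0, z1, depth_step_um)
    flows, speeds = [], []
    step = min(maps.grid.fine_pitch_x, maps.grid.fine_pitch_z) / 2
    for d in depths:
        point, tang = _centerline_at_depth(segment, d)
        _, fvals = _orthogonal_samples(maps.mb_flow, maps.grid, point, tang,
                                       half_width_um, step)
        _, svals = _orthogonal_samples(maps.speed, maps.grid, point, tang,
                                       half_width_um, step)
        flows.append(float(np.sum(fvals) * step))
        speeds.append(float(np.max(svals)) if svals.size else 0.0)
    return DepthProfile(depths_um=depths, mb_flow=np.asarray(flows),
                        speed=np.asarray(speeds))


def measure_diameter(backscatter_map: np.ndarray, grid: GridSpec,
                     segment: VesselSegment, depth_um: float,
                     half_width_um: float = 100.0) -> DiameterResult:
    """Vessel diameter at a depth: FWHM of the orthogonal backscatter
    profile (backscatter delineates the lumen better than MB count).

    Flat or multi-lobed profiles are flagged with no value.
    """
    point, tang = _centerline_at_depth(segment, depth_um)
    step = min(grid.fine_pitch_x, grid.fine_pitch_z) / 4
    offsets, vals = _orthogonal_samples(backscatter_map, grid, point, tang,
                                        half_width_um, step)
    vmax = vals.max() if vals.size else 0.0
    if vmax <= 0:
        return DiameterResult(None, True, "flat profile")
    half = vmax / 2.0
    above = vals >= half
    lobes = np.split(np.flatnonzero(above),
                     np.flatnonzero(np.diff(np.flatnonzero(above)) > 1) + 1)
    lobes = [l for l in lobes if len(l)]
    if len(lobes) != 1:
        return DiameterResult(None, True, f"{len(lobes)} lobes above half maximum")
    idx = lobes[0]
    i0, i1 = idx[0], idx[-1]
    # linear interpolation of the half-max crossings
    left = offsets[i0]
    if i0 > 0 and vals[i0] != vals[i0 - 1]:
        left = np.interp(half, [vals[i0 - 1], vals[i0]],
                         [offsets[i0 - 1], offsets[i0]])
    right = offsets[i1]
    if i1 < len(vals) - 1 and vals[i1] != vals[i1 + 1]:
        right = np.interp(half, [vals[i1 + 1], vals[i1]],
                          [offsets[i1 + 1], offsets[i1]])
    return DiameterResult(float(right - left), False)


def _track_steps_in_mask(tracks: TrackSet, segment: VesselSegment,
                         grid: GridSpec, min_track_len_um: float,
                         roi=None):
    """Unit step vectors of qualifying tracks inside the vessel mask."""
    vecs = []
    n_tracks = 0
    px, pz = grid.fine_pitch_x, grid.fine_pitch_z
    nz, nx = segment.mask.shape
    for tr in tracks.tracks:
        if tr.path_length_um < min_track_len_um:
            continue
        if roi is not None:
            x0, z0, w, h = roi
            if not np.any((tr.x_um >= x0) & (tr.x_um < x0 + w)
                          & (tr.z_um >= z0) & (tr.z_um < z0 + h)):
                continue
        cols = np.clip((tr.x_um / px).astype(int), 0, nx - 1)
        rows = np.clip((tr.z_um / pz).astype(int), 0, nz - 1)
        inside = segment.mask[rows, cols]
        if not np.any(inside[:-1] & inside[1:]):
            continue
        v = compute_velocities(tr, tracks.frame_rate_hz) if len(tr) >= 2 else None
        if v is None:
            continue
        sel = inside[:-1] & inside[1:]
        v = v[sel]
        norms = np.hypot(v[:, 0], v[:, 1])
        v = v[norms > 0] / norms[norms > 0, None]
        if len(v):
            vecs.append(v)
            n_tracks += 1
    return vecs, n_tracks


def tortuosity(segment: VesselSegment, tracks: TrackSet, grid: GridSpec,
               min_track_len_um: float = 100.0, roi=None,
               mode: str = "angle", vessel_id: int = 0) -> TortuosityResult:
    """Tortuosity of a vessel from the dispersion of its velocity vector
    field.

    ``mode='angle'`` (default): circular standard deviation of the flow
    direction angles of all qualifying track steps inside the vessel —
    0 for straight constant-direction flow, rotation- and scale-invariant.
    ``mode='dot'``: standard deviation of scalar products of consecutive
    unit vectors.  Only tracks with path length ≥ ``min_track_len_um``
    (default 0.1 mm) are used; an optional ``roi = (x0, z0, w, h)`` in µm
    restricts the tracks considered.
    """
    vec_lists, n_tracks = _track_steps_in_mask(tracks, segment, grid,
                                               min_track_len_um, roi)
    if not vec_lists:
        raise ValueError(
            f"no qualifying tracks (path length >= {min_track_len_um} µm "
            "inside the vessel mask)")
    all_vecs = np.concatenate(vec_lists, axis=0)
    if mode == "angle":
        angles = np.arctan2(all_vecs[:, 1], all_vecs[:, 0])
        stat = float(circstd(angles, high=np.pi, low=-np.pi))
    elif mode == "dot":
        dots = np.concatenate([np.sum(v[:-1] * v[1:], axis=1)
                               for v in vec_lists if len(v) >= 2])
        stat = float(np.std(dots))
    else:
        raise ValueError(f"unknown tortuosity mode {mode!r}")
    return TortuosityResult(vessel_id=vessel_id, statistic=stat, mode=mode,
                            n_vectors=len(all_vecs), n_tracks=n_tracks)


def roundness(area_um2: float, major_axis_um: float) -> float:
    """Soma roundness: 4·area / (π·major_axis²); 1 for a disc, b/a for an
    ellipse with full axes a ≥ b."""
    if area_um2 <= 0 or major_axis_um <= 0:
        raise ValueError("area and major axis must be positive")
    return 4.0 * area_um2 / (np.pi * major_axis_um ** 2)
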