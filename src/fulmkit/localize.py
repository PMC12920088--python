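"""Per-frame microbubble detection and subpixel localization.

Filtered frames are spatially upsampled ×``interp_factor`` (default 6) with
a Lanczos-3 kernel, cross-correlated (zero-normalized) with a Gaussian
point-spread-function template, and local correlation maxima above the
correlation threshold (default 0.7) are kept.  A 2D second-order polynomial
fit to the 3×3 correlation neighbourhood gives the subpixel position, which
is re-expressed in µm and rasterized on the ×16 fine output grid.  The
filtered-frame magnitude interpolated at the subpixel position is registered
as the bubble's backscatter amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates, maximum_filter, minimum_filter
from skimage.feature import match_template, peak_local_max

from .config import GridSpec
from .stack import FrameStack

__all__ = [
    "Detection",
    "lanczos_matrix",
    "interpolate_frame",
    "gaussian_template",
    "detect_mbs",
    "refine_subpixel",
    "register_backscatter",
    "localize_stack",
]


@dataclass
class Detection:
    """One localized microbubble in one frame."""

    frame: int
    x_um: float
    z_um: float
    corr: float
    backscatter: float = np.nan
    fine_col: int = -1
    fine_row: int = -1
    flagged: bool = False  # subpixel fit fell back to the integer peak


# -- Lanczos-3 resampling -----------------------------------------------------

def lanczos_matrix(n_in: int, factor: int, a: int = 3) -> np.ndarray:
    """(n_in*factor, n_in) Lanczos-a interpolation matrix.

    Output node ``j`` sits at input coordinate ``j / factor``, so original
    samples are preserved at multiples of ``factor``.  Rows are renormalized
    to unit sum to compensate kernel truncation at the edges.
    """
    if factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    n_out = n_in * factor
    pos = np.arange(n_out) / factor
    i = np.arange(n_in)
    x = pos[:, None] - i[None, :]
    with np.errstate(invalid="ignore"):
        w = np.sinc(x) * np.sinc(x / a)
    w[np.abs(x) >= a] = 0.0
    w[np.isclose(x, 0.0)] = 1.0
    norm = w.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return w / norm


def interpolate_frame(frame: np.ndarray, factor: int,
                      matrices: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> np.ndarray:
    """Upsample a 2D frame ×``factor`` per axis with a Lanczos-3 kernel."""
    frame = np.asarray(frame)
    if factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    if factor == 1:
        return frame.copy()
    if matrices is None:
        matrices = (lanczos_matrix(frame.shape[0], factor),
                    lanczos_matrix(frame.shape[1], factor))
    wz, wx = matrices
    return wz @ frame @ wx.T


# -- detection ---------------------------------------------------------------

def gaussian_template(sigma_px: tuple[float, float], half_width_sigmas: float = 2.0
                      ) -> np.ndarray:
    """Unit-peak Gaussian PSF template over a ±2σ window; (rows, cols) =
    (z, x) with per-axis widths ``sigma_px = (sigma_z, sigma_x)``.  The
    window is kept tight so the zero-normalized correlation tolerates the
    smooth background structure the clutter filter leaves around an echo."""
    sz, sx = sigma_px
    hz = max(1, int(np.ceil(half_width_sigmas * sz)))
    hx = max(1, int(np.ceil(half_width_sigmas * sx)))
    z = np.arange(-hz, hz + 1)
    x = np.arange(-hx, hx + 1)
    return np.exp(-0.5 * (z[:, None] / sz) ** 2 - 0.5 * (x[None, :] / sx) ** 2)


def detect_mbs(frame_interp: np.ndarray, psf_sigma_px: tuple[float, float],
               corr_threshold: float = 0.7,
               min_intensity: float = 0.0) -> tuple[list, np.ndarray]:
    """Find candidate bubble peaks on an interpolated frame.

    Zero-normalized cross-correlation with the Gaussian template, then
    8-neighbourhood local maxima above ``corr_threshold``; maxima closer
    than one PSF FWHM are reduced to the single most intense one.  Since
    correlation is amplitude-blind, only the most intense maxima are kept:
    a peak's frame intensity must exceed ``min_intensity`` (callers
    normally pass a noise-adaptive threshold; 0 disables the gate).
    Returns ``(peaks, corr_map)`` where peaks are ``(row, col, corr)``
    integer maxima (border peaks excluded).
    """
    if corr_threshold <= 0 or corr_threshold >= 1:
        raise ValueError("corr_threshold must lie in (0, 1)")
    template = gaussian_template(psf_sigma_px)
    frame64 = frame_interp.astype(np.float64)
    corr = match_template(frame64, template, pad_input=True)
    # the zero-normalized correlation is numerically meaningless where the
    # window holds (near-)constant values; blank those regions
    local_range = (maximum_filter(frame64, size=template.shape)
                   - minimum_filter(frame64, size=template.shape))
    dead = local_range <= 1e-9 * max(float(np.abs(frame64).max()), 1e-300)
    corr[dead] = 0.0
    fwhm = 2.3548 * float(np.mean(psf_sigma_px))
    # peaks need full template support: zero-padded borders produce
    # spuriously normalized correlation values there
    border = max(template.shape) // 2 + 1
    peaks = peak_local_max(corr, min_distance=max(1, int(round(fwhm))),
                           threshold_abs=corr_threshold,
                           exclude_border=border)
    out = [(int(r), int(c), float(corr[r, c])) for r, c in peaks
           if frame_interp[r, c] > min_intensity]
    return out, corr


def refine_subpixel(corr_map: np.ndarray, peak_index: tuple[int, int]
                    ) -> tuple[float, float, bool]:
    """Subpixel peak position from a 2D quadratic fit to the 3×3
    neighbourhood.

    Returns ``(row, col, flagged)`` in (fractional) map coordinates; offsets
    are clamped to ±0.5 px.  A non-concave fit falls back to the integer
    peak with ``flagged=True``.  Border peaks are the caller's problem (they
    are excluded by :func:`detect_mbs`).
    """
    r, c = peak_index
    if not (1 <= r < corr_map.shape[0] - 1 and 1 <= c < corr_map.shape[1] - 1):
        raise ValueError("peak on the map border cannot be refined")
    patch = corr_map[r - 1:r + 2, c - 1:c + 2].astype(np.float64)
    dz, dx = np.mgrid[-1:2, -1:2]
    A = np.stack([np.ones(9), dx.ravel(), dz.ravel(),
                  dx.ravel() ** 2, (dx * dz).ravel(), dz.ravel() ** 2], axis=1)
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    _, b, cc, d, e, g = coef
    hess_det = 4 * d * g - e * e
    if d >= 0 or g >= 0 or hess_det <= 0:
        return float(r), float(c), True
    ox = (-2 * g * b + e * cc) / hess_det
    oz = (-2 * d * cc + e * b) / hess_det
    ox = float(np.clip(ox, -0.5, 0.5))
    oz = float(np.clip(oz, -0.5, 0.5))
    return r + oz, c + ox, False


def register_backscatter(frame_interp: np.ndarray, row: float, col: float) -> float:
    """Interpolated frame magnitude at a (fractional) position (cubic
    spline, so the value at an echo's subpixel peak is not clipped to the
    nearest grid sample)."""
    return float(map_coordinates(np.abs(frame_interp), [[row], [col]],
                                 order=3, mode="nearest")[0])


# -- whole-stack convenience --------------------------------------------------

def localize_stack(
    stack: FrameStack,
    psf_sigma_um: float,
    corr_threshold: float = 0.7,
    frame_offset: int = 0,
    noise_mult: float = 2.5,
    interp_matrices=None,
) -> pd.DataFrame:
    """Localize bubbles in every frame of a (filtered) stack.

    Real-valued filtered frames are correlated in their signed form (a
    bubble echo is a positive lobe; noise is half negative, so far fewer
    noise bumps pass the shape test than on the rectified magnitude);
    complex IQ stacks fall back to the magnitude.  Peaks must clear both
    the correlation threshold and an intensity gate of ``noise_mult``
    robust noise standard deviations (median absolute deviation of the
    frame), which keeps only the most intense maxima.  Returns a detection
    table with columns frame, t_s, x_um, z_um, corr, backscatter,
    fine_col, fine_row, flagged.  ``frame_offset`` shifts the reported
    frame indices (useful when a stack is a trimmed sub-acquisition).
    """
    grid = stack.grid
    m = grid.interp_factor
    pitch_x = grid.native_pitch_x / m
    pitch_z = grid.native_pitch_z / m
    sigma_px = (psf_sigma_um / pitch_z, psf_sigma_um / pitch_x)
    mats = interp_matrices or (lanczos_matrix(grid.n_z_native, m),
                               lanczos_matrix(grid.n_x_native, m))
    is_complex = np.iscomplexobj(stack.values)
    rows = []
    for f in range(stack.n_frames):
        raw = stack.values[:, :, f]
        frame = np.abs(raw).astype(np.float64) if is_complex \
            else raw.astype(np.float64)
        mad = np.median(np.abs(frame - np.median(frame)))
        gate = noise_mult * 1.4826 * mad
        up = interpolate_frame(frame, m, mats)
        peaks, corr = detect_mbs(up, sigma_px, corr_threshold,
                                 min_intensity=gate)
        for (r, c, cv) in peaks:
            rr, cc, flagged = refine_subpixel(corr, (r, c))
            x_um = cc * pitch_x
            z_um = rr * pitch_z
            amp = register_backscatter(up, rr, cc)
            fine_col, fine_row = grid.fine_pixel(x_um, z_um)
            rows.append((f + frame_offset, x_um, z_um, cv, amp,
                         int(fine_col), int(fine_row), flagged))
    df = pd.DataFrame(rows, columns=["frame", "x_um", "z_um", "corr",
                                     "backscatter", "fine_col", "fine_row",
                                     "flagged"])
    df["t_s"] = df["frame"] / stack.frame_rate_hz
    return df
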