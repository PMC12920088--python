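"""Microscopic-scale (fULM) activation maps, depth-resolved activation
signals, and pattern/acquisition quality control.

The activation map is the relative microbubble-flow increase
``(stim − baseline) / baseline`` per fine pixel, defined only where
baseline flow is non-zero.  Activation signals average MB flow over a
vessel mask split at 400 µm depth (SMC-covered arteriolar segments above,
pericyte-covered arteriole–capillary-transition zone below), normalized to
the pattern's baseline (100%).  QC follows fixed rules: a pattern is kept
iff its arteriolar MB-count signal correlates > 0.3 with the stimulus
boxcar, a contralateral control signal stays within ±0.5 correlation, and
global bubble flux is stable (coefficient of variation < 0.3 — the
automated stand-in for manual pattern pre-selection); an acquisition is
kept iff the pattern-averaged signal reaches a 10% stimulation increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StimulusProtocol
from .maps import PatternAveragedStack, ULMMaps
from .tracking import TrackSet

__all__ = [
    "ActivationMap",
    "ActivationSignal",
    "PatternQCReport",
    "activation_map",
    "activation_signal",
    "pattern_qc",
    "track_windows",
]


@dataclass
class ActivationMap:
    """Relative MB-flow increase per fine pixel (dimensionless fraction)."""

    values: np.ndarray  # (stim - base)/base where defined, 0 elsewhere
    defined: np.ndarray  # boolean mask: baseline flow > 0
    baseline: ULMMaps
    stimulation: ULMMaps


@dataclass
class ActivationSignal:
    """Depth-band activation signal over the averaged pattern."""

    band: str  # e.g. "0-400um" | "400um-bottom"
    t_s: np.ndarray  # window start times within the pattern
    signal_percent: np.ndarray  # baseline-normalized MB flow, % (baseline=100)
    early_percent: float  # mean increase over the early window
    late_percent: float
    early_window_s: tuple[float, float] = (30.0, 40.0)
    late_window_s: tuple[float, float] = (40.0, 60.0)


@dataclass
class PatternQCReport:
    """Per-pattern and acquisition-level QC decisions."""

    per_pattern: pd.DataFrame  # pattern, stim_corr, contra_corr, flux_cv, kept, reason
    mean_stim_increase_percent: float
    acquisition_kept: bool
    thresholds: dict


def activation_map(baseline: ULMMaps, stim: ULMMaps) -> ActivationMap:
    """(stim − baseline)/baseline flow per pixel; pixels with zero baseline
    flow are masked out rather than assigned infinity."""
    if baseline.mb_flow.shape != stim.mb_flow.shape:
        raise ValueError("baseline and stimulation maps are on different grids")
    defined = baseline.mb_flow > 0
    values = np.zeros_like(baseline.mb_flow)
    values[defined] = (stim.mb_flow[defined] - baseline.mb_flow[defined]) \
        / baseline.mb_flow[defined]
    return ActivationMap(values=values, defined=defined,
                         baseline=baseline, stimulation=stim)


def activation_signal(stack: PatternAveragedStack, vessel_mask: np.ndarray,
                      protocol: StimulusProtocol,
                      depth_split_um: float = 400.0,
                      band: str = "deep",
                      early_window_s: tuple[float, float] = (30.0, 40.0),
                      late_window_s: tuple[float, float] = (40.0, 60.0)
                      ) -> ActivationSignal:
    """Activation signal for one depth band of a vessel mask.

    ``band='upper'`` is 0–``depth_split_um``; ``band='deep'`` is below the
    split.  The per-window spatial mean of MB flow over mask ∩ band is
    normalized so the 0–rest window mean is 100%.
    """
    grid = stack.grid
    nz, nx = vessel_mask.shape
    depths = (np.arange(nz) + 0.5) * grid.fine_pitch_z
    if band == "upper":
        band_mask = depths < depth_split_um
        label = f"0-{depth_split_um:g}um"
    elif band == "deep":
        band_mask = depths >= depth_split_um
        label = f"{depth_split_um:g}um-bottom"
    else:
        raise ValueError("band must be 'upper' or 'deep'")
    mask = vessel_mask & band_mask[:, None]
    if not np.any(mask):
        raise ValueError(f"empty mask in depth band {label}")
    t = np.array([m.window[0] for m in stack.maps])
    raw = np.array([float(m.mb_flow[mask].mean()) for m in stack.maps])
    base_sel = t < protocol.rest_s
    base = raw[base_sel].mean()
    if base <= 0:
        raise ValueError(f"zero baseline flow in depth band {label}")
    sig = 100.0 * raw / base

    def mean_increase(win):
        sel = (t >= win[0]) & (t < win[1])
        return float(sig[sel].mean() - 100.0) if np.any(sel) else np.nan

    return ActivationSignal(band=label, t_s=t, signal_percent=sig,
                            early_percent=mean_increase(early_window_s),
                            late_percent=mean_increase(late_window_s),
                            early_window_s=early_window_s,
                            late_window_s=late_window_s)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pattern_qc(roi_signals: np.ndarray, contra_signals: np.ndarray,
               global_signals: np.ndarray, protocol: StimulusProtocol,
               window_s: float = 2.0,
               stim_corr_threshold: float = 0.3,
               contra_corr_band: float = 0.5,
               min_increase_percent: float = 10.0,
               flux_cv_threshold: float = 0.3) -> PatternQCReport:
    """Apply the pattern- and acquisition-level QC rules.

    Inputs are (n_patterns, n_windows_per_pattern) arrays of the arteriole
    ROI MB-count signal, the contralateral control-ROI signal, and the
    whole-image MB count.  A pattern is kept iff its ROI signal's Pearson
    correlation with the binary stimulus boxcar exceeds the threshold, the
    contralateral correlation lies within ±``contra_corr_band``, and the
    whole-image flux CV is below ``flux_cv_threshold``; zero-variance
    signals are rejected with a reason.  The acquisition is kept iff the
    kept-pattern-averaged ROI signal's mean stimulation increase reaches
    ``min_increase_percent``.
    """
    roi_signals = np.atleast_2d(np.asarray(roi_signals, float))
    contra_signals = np.atleast_2d(np.asarray(contra_signals, float))
    global_signals = np.atleast_2d(np.asarray(global_signals, float))
    n_pat, n_win = roi_signals.shape
    t = np.arange(n_win) * window_s
    boxcar = ((t >= protocol.rest_s)
              & (t < protocol.rest_s + protocol.stim_s)).astype(float)

    rows = []
    for p in range(n_pat):
        stim_corr = _pearson(roi_signals[p], boxcar)
        contra_corr = _pearson(contra_signals[p], boxcar)
        g = global_signals[p]
        cv = float(g.std() / g.mean()) if g.mean() > 0 else np.inf
        reason = ""
        if np.isnan(stim_corr):
            kept, reason = False, "zero-variance ROI signal"
        elif stim_corr <= stim_corr_threshold:
            kept, reason = False, "stimulus correlation below threshold"
        elif np.isnan(contra_corr):
            kept, reason = False, "zero-variance contralateral signal"
        elif abs(contra_corr) > contra_corr_band:
            kept, reason = False, "contralateral correlation out of band"
        elif cv >= flux_cv_threshold:
            kept, reason = False, "unstable global bubble flux"
        else:
            kept = True
        rows.append((p, stim_corr, contra_corr, cv, kept, reason))
    report = pd.DataFrame(rows, columns=["pattern", "stim_corr", "contra_corr",
                                         "flux_cv", "kept", "reason"])

    kept_idx = report.index[report["kept"]].to_numpy()
    if len(kept_idx):
        avg = roi_signals[kept_idx].mean(axis=0)
        base = avg[t < protocol.rest_s].mean()
        stim_sel = boxcar > 0
        increase = 100.0 * (avg[stim_sel].mean() - base) / base if base > 0 else 0.0
    else:
        increase = 0.0
    return PatternQCReport(
        per_pattern=report,
        mean_stim_increase_percent=float(increase),
        acquisition_kept=bool(increase >= min_increase_percent),
        thresholds={"stim_corr": stim_corr_threshold,
                    "contra_corr_band": contra_corr_band,
                    "min_increase_percent": min_increase_percent,
                    "flux_cv": flux_cv_threshold},
    )


def track_windows(tracks: TrackSet, window_s: float = 4.0, t0_s: float = 0.0
                  ) -> dict[int, list]:
    """Group tracks into consecutive windows by first-detection time,
    for raw-track overlays on cumulative activation maps."""
    if window_s <= 0:
        raise ValueError("window must be positive")
    bundles: dict[int, list] = {}
    for tr in tracks.tracks:
        t_first = tr.frames[0] / tracks.frame_rate_hz
        k = int(np.floor((t_first - t0_s) / window_s))
        bundles.setdefault(k, []).append(tr)
    return bundles
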