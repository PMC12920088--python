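"""Accumulation of track presence marks into super-resolved ULM maps.

``mb_flow`` counts microbubble presence marks per fine pixel per second
(MBs px⁻¹ s⁻¹); velocity components, scalar speed and backscatter are
presence-weighted means over the marks in the window (exactly 0 where no
bubble was seen).  Dynamic stacks accumulate consecutive non-overlapping
2-s windows; pattern-averaged stacks recombine the windows of the kept
stimulation patterns by within-pattern time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GridSpec, StimulusProtocol
from .tracking import TrackSet, rasterize_tracks

__all__ = [
    "ULMMaps",
    "DynamicULMStack",
    "PatternAveragedStack",
    "accumulate_marks",
    "accumulate_maps",
    "dynamic_stack",
    "pattern_average",
    "pattern_average_from_tracks",
    "split_baseline_stim",
    "display_transform",
]


@dataclass
class ULMMaps:
    """Co-registered fine-grid maps for one accumulation window."""

    mb_flow: np.ndarray  # MBs px^-1 s^-1
    vx: np.ndarray  # mm/s, presence-weighted mean
    vz: np.ndarray
    speed: np.ndarray  # mm/s scalar mean, 0 where mb_flow == 0
    backscatter: np.ndarray
    window: tuple[float, float]  # (start_s, end_s)
    grid: GridSpec

    @property
    def counts(self) -> np.ndarray:
        """Raw presence counts = mb_flow × window duration."""
        return self.mb_flow * (self.window[1] - self.window[0])


@dataclass
class DynamicULMStack:
    """Per-window ULMMaps over a whole acquisition (window default 2 s)."""

    maps: list[ULMMaps]
    window_s: float
    grid: GridSpec

    def __len__(self) -> int:
        return len(self.maps)

    def flow_array(self) -> np.ndarray:
        return np.stack([m.mb_flow for m in self.maps], axis=2)


@dataclass
class PatternAveragedStack:
    """ULMMaps per within-pattern time index, averaged over kept patterns."""

    maps: list[ULMMaps]
    window_s: float
    kept_patterns: list[int]
    grid: GridSpec

    def __len__(self) -> int:
        return len(self.maps)


def _empty(shape):
    return np.zeros(shape, dtype=np.float64)


def accumulate_marks(marks: pd.DataFrame, grid: GridSpec,
                     window: tuple[float, float]) -> ULMMaps:
    """Accumulate presence marks with ``t_s`` in [start, end) into maps."""
    start, end = window
    sel = marks[(marks["t_s"] >= start) & (marks["t_s"] < end)] if len(marks) else marks
    return _accumulate_selected(sel, grid, window)


def _accumulate_selected(sel: pd.DataFrame, grid: GridSpec,
                         window: tuple[float, float]) -> ULMMaps:
    """Accumulate an already time-filtered mark subset."""
    start, end = window
    duration = end - start
    if duration <= 0:
        raise ValueError("window duration must be positive")
    shape = (grid.n_z_fine, grid.n_x_fine)
    count = _empty(shape)
    if len(sel) == 0:
        zero = _empty(shape)
        return ULMMaps(mb_flow=count, vx=zero.copy(), vz=zero.copy(),
                       speed=zero.copy(), backscatter=zero.copy(),
                       window=window, grid=grid)
    rows = sel["row"].to_numpy(dtype=int)
    cols = sel["col"].to_numpy(dtype=int)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    rows, cols = rows[ok], cols[ok]
    sel = sel.iloc[np.flatnonzero(ok)]
    flat = rows * shape[1] + cols
    n = shape[0] * shape[1]
    count = np.bincount(flat, minlength=n).astype(np.float64)

    def mean_of(col_name):
        w = sel[col_name].to_numpy(dtype=float)
        w = np.nan_to_num(w)
        s = np.bincount(flat, weights=w, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(count > 0, s / np.maximum(count, 1), 0.0)
        return m.reshape(shape)

    return ULMMaps(
        mb_flow=(count / duration).reshape(shape),
        vx=mean_of("vx_mm_s"),
        vz=mean_of("vz_mm_s"),
        speed=mean_of("speed_mm_s"),
        backscatter=mean_of("backscatter"),
        window=window,
        grid=grid,
    )


def accumulate_maps(tracks: TrackSet, grid: GridSpec,
                    window: tuple[float, float]) -> ULMMaps:
    """Rasterize a TrackSet and accumulate one window into ULMMaps."""
    return accumulate_marks(rasterize_tracks(tracks, grid), grid, window)


def dynamic_stack(tracks: TrackSet, grid: GridSpec, duration_s: float,
                  window_s: float = 2.0) -> DynamicULMStack:
    """One ULMMaps per consecutive non-overlapping window over the
    acquisition; ``duration_s`` must be a multiple of ``window_s``."""
    n = duration_s / window_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"duration {duration_s} s is not a multiple of the {window_s} s window")
    n = int(round(n))
    marks = rasterize_tracks(tracks, grid)
    if len(marks):
        widx = np.floor(marks["t_s"].to_numpy() / window_s).astype(int)
        groups = {k: g for k, g in marks.groupby(widx)}
    else:
        groups = {}
    empty = marks.iloc[:0] if len(marks) else marks
    maps = [_accumulate_selected(groups.get(k, empty), grid,
                                 (k * window_s, (k + 1) * window_s))
            for k in range(n)]
    return DynamicULMStack(maps=maps, window_s=window_s, grid=grid)


def pattern_average(stack: DynamicULMStack, protocol: StimulusProtocol,
                    kept_patterns: list[int] | None = None
                    ) -> PatternAveragedStack:
    """Average the dynamic stack over (kept) stimulation patterns.

    Counts are averaged per within-pattern time index; speeds, velocity
    components and backscatter are density-weighted means (each pattern's
    contribution weighted by its counts).
    """
    per_pattern = protocol.n_windows_per_pattern(stack.window_s)
    n_patterns = len(stack.maps) // per_pattern
    if kept_patterns is None:
        kept_patterns = list(range(n_patterns))
    if not kept_patterns:
        raise ValueError("kept_patterns must be a non-empty subset")
    if max(kept_patterns) >= n_patterns:
        raise ValueError("kept pattern index beyond available patterns")
    out = []
    for j in range(per_pattern):
        members = [stack.maps[p * per_pattern + j] for p in kept_patterns]
        counts = np.stack([m.counts for m in members], axis=2)
        total = counts.sum(axis=2)
        flow = total / (stack.window_s * len(members))

        def wmean(attr):
            vals = np.stack([getattr(m, attr) for m in members], axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                out_ = np.where(total > 0,
                                (vals * counts).sum(axis=2) / np.maximum(total, 1e-300),
                                0.0)
            return out_

        out.append(ULMMaps(
            mb_flow=flow, vx=wmean("vx"), vz=wmean("vz"),
            speed=wmean("speed"), backscatter=wmean("backscatter"),
            window=(j * stack.window_s, (j + 1) * stack.window_s),
            grid=stack.grid))
    return PatternAveragedStack(maps=out, window_s=stack.window_s,
                                kept_patterns=list(kept_patterns),
                                grid=stack.grid)


def pattern_average_from_tracks(tracks: TrackSet, grid: GridSpec,
                                protocol: StimulusProtocol,
                                window_s: float = 2.0,
                                kept_patterns: list[int] | None = None,
                                duration_s: float | None = None
                                ) -> PatternAveragedStack:
    """Pattern-averaged stack computed directly from track marks.

    Equivalent to ``pattern_average(dynamic_stack(...))`` but accumulates
    each within-pattern time index in one pass, which avoids materializing
    the full dynamic stack for long multi-pattern acquisitions.
    """
    per_pattern = protocol.n_windows_per_pattern(window_s)
    if duration_s is None:
        duration_s = protocol.total_duration_s
    n_patterns = int(duration_s // protocol.pattern_duration_s)
    if kept_patterns is None:
        kept_patterns = list(range(n_patterns))
    if not kept_patterns:
        raise ValueError("kept_patterns must be a non-empty subset")
    kept = np.zeros(n_patterns, dtype=bool)
    kept[np.asarray(kept_patterns, dtype=int)] = True

    marks = rasterize_tracks(tracks, grid)
    if len(marks):
        t = marks["t_s"].to_numpy()
        pat = np.floor(t / protocol.pattern_duration_s).astype(int)
        ok = (pat < n_patterns) & kept[np.clip(pat, 0, n_patterns - 1)]
        marks = marks.iloc[np.flatnonzero(ok)]
        t_in = np.mod(marks["t_s"].to_numpy(), protocol.pattern_duration_s)
        widx = np.floor(t_in / window_s).astype(int)
        groups = {k: g for k, g in marks.groupby(widx)}
    else:
        groups = {}
    empty = marks.iloc[:0] if len(marks) else marks
    n_kept = int(kept.sum())
    out = []
    for j in range(per_pattern):
        g = groups.get(j, empty)
        # accumulating over n_kept repetitions of the same window
        m = _accumulate_selected(g, grid, (0.0, window_s * n_kept))
        out.append(ULMMaps(mb_flow=m.mb_flow, vx=m.vx, vz=m.vz,
                           speed=m.speed, backscatter=m.backscatter,
                           window=(j * window_s, (j + 1) * window_s),
                           grid=grid))
    return PatternAveragedStack(maps=out, window_s=window_s,
                                kept_patterns=[int(p) for p in
                                               np.flatnonzero(kept)],
                                grid=grid)


def split_baseline_stim(tracks: TrackSet, grid: GridSpec,
                        protocol: StimulusProtocol,
                        duration_s: float | None = None
                        ) -> tuple[ULMMaps, ULMMaps]:
    """Baseline (0–rest) vs stimulation (rest–rest+stim) maps by
    pattern-relative mark time; the trailing post window is excluded from
    both.  Flow is normalized by the total accumulated duration of each
    subset."""
    marks = rasterize_tracks(tracks, grid)
    if duration_s is None:
        duration_s = protocol.total_duration_s
    n_patterns = int(np.ceil(duration_s / protocol.pattern_duration_s))
    t_in = np.mod(marks["t_s"].to_numpy(dtype=float), protocol.pattern_duration_s) \
        if len(marks) else np.array([])

    def subset(mask, window_len):
        sub = marks.iloc[np.flatnonzero(mask)] if len(marks) else marks
        sub = sub.copy()
        # fold each pattern's window onto one contiguous accumulation span
        total = window_len * n_patterns
        if len(sub):
            sub["t_s"] = 0.0  # all marks inside the single accumulation window
        return accumulate_marks(sub, grid, (0.0, total))

    base = subset(t_in < protocol.rest_s, protocol.rest_s) if len(marks) else \
        accumulate_marks(marks, grid, (0.0, protocol.rest_s * n_patterns))
    stim_mask = (t_in >= protocol.rest_s) & (t_in < protocol.rest_s + protocol.stim_s)
    stim = subset(stim_mask, protocol.stim_s) if len(marks) else \
        accumulate_marks(marks, grid, (0.0, protocol.stim_s * n_patterns))
    return base, stim


def display_transform(mb_flow: np.ndarray) -> np.ndarray:
    """Square root of the density, for display only (compresses dynamic
    range so the smallest vessels stay visible); analysis always uses the
    linear values."""
    arr = np.asarray(mb_flow, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mb_flow must be non-negative")
    return np.sqrt(arr)
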