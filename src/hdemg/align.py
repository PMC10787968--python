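"""Aligning cue labels to actual EMG activity.

Subjects react late (and release late) relative to on-screen cues, and
after stroke these latencies are large and variable; labels taken directly
from cue timing therefore mislabel transition bins. Two remedies:

* a static shift of all boundaries by a fixed reaction-time estimate;
* dynamic shifting — treat the across-channel mean of the normalized RMS
  as a piecewise-constant signal segmented by the cue boundaries, and move
  each boundary (up to 2 s, on the 100 ms bin grid) to minimize the sum of
  squared residuals around the per-segment means.

The dynamic optimizer is exhaustive coordinate descent: boundaries are
swept in temporal order, each placed at its best grid position given its
neighbours, repeated until a sweep moves nothing (or 50 sweeps). Ties are
broken toward the smaller shift, so an already-aligned boundary stays put.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BIN_WIDTH_S, FeatureTensor
from .simulate import CueSchedule


def summarize(ft: FeatureTensor) -> np.ndarray:
    """Per-bin mean of the (normalized) RMS across channels."""
    if ft.rms.size == 0:
        raise ValueError("empty feature tensor")
    return ft.rms.mean(axis=1)


@dataclass(frozen=True)
class ShiftResult:
    shifted_schedule: CueSchedule
    per_boundary_shift_s: np.ndarray
    total_ssr: float
    initial_ssr: float
    iterations: int


def _segment_sse(prefix1: np.ndarray, prefix2: np.ndarray, a: int, b: int) -> float:
    """Sum of squared residuals of bins [a, b) around their mean (O(1))."""
    n = b - a
    s1 = prefix1[b] - prefix1[a]
    s2 = prefix2[b] - prefix2[a]
    return s2 - s1 * s1 / n


def total_ssr(summary: np.ndarray, bounds: np.ndarray) -> float:
    """Objective: within-segment squared residuals for boundary bins ``bounds``."""
    p1 = np.concatenate([[0.0], np.cumsum(summary)])
    p2 = np.concatenate([[0.0], np.cumsum(summary**2)])
    edges = [0, *bounds.tolist(), summary.size]
    return float(sum(_segment_sse(p1, p2, edges[i], edges[i + 1]) for i in range(len(edges) - 1)))


def dynamic_shift(
    summary: np.ndarray,
    schedule: CueSchedule,
    max_shift_s: float = 2.0,
    forward_only: bool = False,
    max_sweeps: int = 50,
) -> ShiftResult:
    """Move segment boundaries to minimize within-segment squared residuals.

    Constraints: each boundary moves at most ``max_shift_s`` from its cued
    position, boundaries stay strictly ordered, and every segment keeps at
    least one bin. Labels, segment count and order never change.
    """
    if max_shift_s < 0:
        raise ValueError("max_shift_s must be non-negative")
    if len(schedule.segments) < 2:
        raise ValueError("need at least two segments to shift boundaries")
    n_bins = summary.size
    need = int(np.floor(schedule.duration_s / BIN_WIDTH_S))
    if n_bins < need:
        raise ValueError(
            f"summary ({n_bins} bins) does not cover the schedule ({need} bins)"
        )

    orig = np.round(schedule.boundaries_s / BIN_WIDTH_S).astype(int)
    bounds = orig.copy()
    max_move = int(round(max_shift_s / BIN_WIDTH_S))
    p1 = np.concatenate([[0.0], np.cumsum(summary)])
    p2 = np.concatenate([[0.0], np.cumsum(summary**2)])

    init_ssr = total_ssr(summary, bounds)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        moved = False
        for j in range(bounds.size):
            left = bounds[j - 1] if j > 0 else 0
            right = bounds[j + 1] if j + 1 < bounds.size else n_bins
            lo = max(left + 1, orig[j] - (0 if forward_only else max_move))
            hi = min(right - 1, orig[j] + max_move)
            if lo > hi:
                continue
            best_pos, best_key = bounds[j], None
            for pos in range(lo, hi + 1):
                sse = _segment_sse(p1, p2, left, pos) + _segment_sse(p1, p2, pos, right)
                shift = pos - orig[j]
                key = (sse, abs(shift), shift)
                if best_key is None or key < best_key:
                    best_key, best_pos = key, pos
            if best_pos != bounds[j]:
                bounds[j] = best_pos
                moved = True
        if not moved:
            break

    shifts = (bounds - orig) * BIN_WIDTH_S
    shifted = schedule.with_boundaries(bounds * BIN_WIDTH_S)
    return ShiftResult(
        shifted_schedule=shifted,
        per_boundary_shift_s=shifts,
        total_ssr=total_ssr(summary, bounds),
        initial_ssr=init_ssr,
        iterations=sweeps,
    )


def static_shift(schedule: CueSchedule, delta_s: float) -> CueSchedule:
    """Translate every interior boundary by ``delta_s`` (record ends fixed)."""
    if not np.isfinite(delta_s):
        raise ValueError("shift must be finite")
    min_dur = min(s.duration_s for s in schedule.segments)
    if abs(delta_s) >= min_dur:
        raise ValueError(
            f"shift {delta_s} s would collapse a segment (min duration {min_dur} s)"
        )
    bounds = np.clip(schedule.boundaries_s + delta_s, 0.0, schedule.duration_s)
    return schedule.with_boundaries(bounds)


def shift_fraction(
    original: CueSchedule, shifted: CueSchedule, bin_width_s: float = BIN_WIDTH_S
) -> tuple[float, float]:
    """(fraction of bins relabelled, mean absolute boundary shift in s)."""
    if not np.isclose(original.duration_s, shifted.duration_s):
        raise ValueError("schedules cover different extents")
    n_bins = int(np.floor(original.duration_s / bin_width_s))
    a = original.labels_for_bins(n_bins, bin_width_s)
    b = shifted.labels_for_bins(n_bins, bin_width_s)
    frac = float(np.mean(a != b))
    mean_shift = float(np.mean(np.abs(shifted.boundaries_s - original.boundaries_s)))
    return frac, mean_shift
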