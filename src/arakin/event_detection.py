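"""Detect single-RNA production events in total-spot-intensity traces.

A cell's total spot intensity is fit with a monotone (non-decreasing)
piecewise-constant function by least squares.  For each candidate segment
count k the globally optimal partition is found by dynamic programming
over breakpoints; a partition whose segment means decrease anywhere is
repaired by pooling adjacent segments (weighted isotonic regression).
The number of segments is selected forward by a nested F-test: stop at
the first k for which k segments do not significantly improve on k - 1.
Each upward jump of the selected fit is one RNA production event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "IntensityTrace",
    "PiecewiseFit",
    "EventSeries",
    "fit_monotone_pwc",
    "extract_events",
    "detect_population",
]


@dataclass
class IntensityTrace:
    """One cell's intensity time series on a regular frame grid."""

    cell_id: int
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if (dt <= 0).any() or not np.allclose(dt, dt[0]):
                raise ValueError("times must be strictly increasing on a regular grid")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class PiecewiseFit:
    """Monotone piecewise-constant least-squares fit of a trace.

    ``breakpoints[j]`` is the frame index at which segment j+1 starts (the
    jump occurs between frames ``breakpoints[j] - 1`` and ``breakpoints[j]``).
    """

    breakpoints: np.ndarray      # int indices, strictly increasing, len = n_segments-1
    levels: np.ndarray           # non-decreasing segment means
    segment_sse: np.ndarray
    sse: float
    n_segments: int


@dataclass
class EventSeries:
    """Per-cell production times, waiting time t0 and intervals."""

    cell_id: int
    t0: float | None
    production_times: np.ndarray
    intervals: np.ndarray
    excluded_t0: bool = False
    exclusion_reason: str = ""


def _optimal_partitions(y: np.ndarray, k_max: int):
    """DP over breakpoints: least-squares cost of the best j-segment fit of
    y[:i] for all prefixes i and all j <= k_max.  Returns (cost, argmin)."""
    T = y.size
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of y[i:j] about its mean, vectorized over start indices i
        n = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / n

    cost = np.full((k_max + 1, T + 1), np.inf)
    arg = np.zeros((k_max + 1, T + 1), dtype=int)
    for j in range(1, T + 1):
        cost[1, j] = seg_cost(np.array([0]), j)[0]
    for k in range(2, k_max + 1):
        for j in range(k, T + 1):
            i = np.arange(k - 1, j)      # last segment is y[i:j]
            tot = cost[k - 1, i] + seg_cost(i, j)
            m = int(np.argmin(tot))
            cost[k, j] = tot[m]
            arg[k, j] = i[m]
    return cost, arg


def _backtrack(arg: np.ndarray, k: int, T: int) -> list[int]:
    bps: list[int] = []
    j = T
    for kk in range(k, 1, -1):
        j = int(arg[kk, j])
        bps.append(j)
    return bps[::-1]


def _isotonic_repair(y: np.ndarray, bps: list[int]) -> PiecewiseFit:
    """Build the fit for given breakpoints, pooling segments whose means
    decrease (weighted isotonic regression), then merging equal levels."""
    from scipy.optimize import isotonic_regression

    T = y.size
    edges = [0] + list(bps) + [T]
    means = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    weights = np.diff(edges).astype(float)
    if means.size > 1 and (np.diff(means) < 0).any():
        means = isotonic_regression(means, weights=weights).x
    # merge adjacent segments with (now) equal levels
    keep_bps: list[int] = []
    levels: list[float] = []
    for j, m in enumerate(means):
        if levels and np.isclose(m, levels[-1], rtol=0, atol=1e-12 * (1 + abs(m))):
            continue
        if j > 0:
            keep_bps.append(edges[j])
        levels.append(m)
    edges2 = [0] + keep_bps + [T]
    levels_arr = np.array(levels)
    seg_sse = np.array([np.sum((y[a:b] - lv) ** 2)
                        for (a, b), lv in zip(zip(edges2[:-1], edges2[1:]), levels_arr)])
    return PiecewiseFit(
        breakpoints=np.asarray(keep_bps, dtype=int),
        levels=levels_arr,
        segment_sse=seg_sse,
        sse=float(seg_sse.sum()),
        n_segments=len(levels),
    )


def fit_monotone_pwc(trace: IntensityTrace, max_segments: int = 12,
                     alpha: float = 0.01) -> PiecewiseFit:
    """Monotone piecewise-constant least-squares fit with F-test selection.

    Parameters
    ----------
    trace:
        Intensity trace with at least 3 frames.
    max_segments:
        Upper bound on the number of constant segments.
    alpha:
        Significance level of the nested F-test adding one segment at a
        time (default 0.01).  Each added segment costs two parameters
        (one level, one breakpoint): the statistic comparing k with k - 1
        segments is ``F = ((SSE_{k-1} - SSE_k)/2) / (SSE_k/(T - 2k))``
        on (2, T - 2k) degrees of freedom.

    Returns
    -------
    PiecewiseFit
        The selected fit; levels are non-decreasing by construction.
    """
    y = np.asarray(trace.intensities, dtype=float)
    T = y.size
    if T < 3:
        raise ValueError("trace must have at least 3 frames")
    if not np.isfinite(y).all():
        raise ValueError("trace contains non-finite intensities")
    k_max = int(min(max_segments, T))
    if k_max < 1:
        raise ValueError("max_segments must be >= 1")

    cost, arg = _optimal_partitions(y, k_max)
    best = _isotonic_repair(y, [])
    for k in range(2, k_max + 1):
        cand = _isotonic_repair(y, _backtrack(arg, k, T))
        df2 = T - 2 * k
        if df2 <= 0:
            break
        prev_sse, new_sse = best.sse, cand.sse
        if prev_sse <= 0:
            break  # already perfect
        if new_sse <= 0:
            p = 0.0
        else:
            f = ((prev_sse - new_sse) / 2.0) / (new_sse / df2)
            p = float(stats.f.sf(f, 2, df2)) if f > 0 else 1.0
        if p >= alpha:
            break
        if cand.n_segments > best.n_segments:
            best = cand
    return best


def extract_events(fit: PiecewiseFit, trace: IntensityTrace,
                   induction_time: float = 0.0,
                   unit_intensity: float | None = None,
                   quantize: bool = False) -> EventSeries:
    """Convert the jumps of a fit into RNA production events.

    Each jump is one production event timed at the first frame of the new
    segment.  ``t0`` is the first event time minus ``induction_time``.
    Cells whose first segment level exceeds half the unit intensity carried
    RNA before induction: their ``t0`` is excluded (flagged) but intervals
    are kept.  The partial interval from the last event to the end of the
    trace is right-censored and never emitted.

    With ``quantize=True`` each jump emits ``round(amplitude/unit)`` (at
    least 1) simultaneous productions; intervals are still measured
    between successive jump times.
    """
    jump_times = trace.times[fit.breakpoints]
    amplitudes = np.diff(fit.levels)

    if quantize:
        if unit_intensity is None:
            raise ValueError("quantize=True requires unit_intensity")
        counts = np.maximum(1, np.round(amplitudes / unit_intensity).astype(int))
    else:
        counts = np.ones(jump_times.size, dtype=int)
    production_times = np.repeat(jump_times, counts)

    intervals = np.diff(jump_times)

    excluded = False
    reason = ""
    t0: float | None = None
    if jump_times.size == 0:
        reason = "no_event"
    elif unit_intensity is not None and fit.levels[0] > 0.5 * unit_intensity:
        excluded = True
        reason = "preexisting_rna"
    else:
        t0 = float(jump_times[0] - induction_time)

    return EventSeries(
        cell_id=trace.cell_id,
        t0=t0,
        production_times=production_times,
        intervals=intervals,
        excluded_t0=excluded,
        exclusion_reason=reason,
    )


def detect_population(traces, max_segments: int = 12, alpha: float = 0.01,
                      induction_time: float = 0.0,
                      unit_intensity: float | None = None,
                      quantize: bool = False) -> list[EventSeries]:
    """Fit and extract events for every trace in a population."""
    out = []
    for tr in traces:
        fit = fit_monotone_pwc(tr, max_segments=max_segments, alpha=alpha)
        out.append(extract_events(fit, tr, induction_time=induction_time,
                                  unit_intensity=unit_intensity, quantize=quantize))
    return out
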