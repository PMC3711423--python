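"""Summary statistics and tests for waiting times (t0) and intervals (dt).

The waiting time t0 of a cell runs from induction to its first RNA; dt
are the intervals between its subsequent productions.  Because both are
of the same order as the observation window, naive per-cell correlation
of t0 with dt is biased negative (cells that start late cannot show long
intervals).  The windowed analysis removes this: only cells whose t0
leaves a full window W of observation are kept, and only events within
[t0, t0 + W] are used, so the effective observation length is identical
for every retained cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .event_detection import EventSeries

__all__ = [
    "SampleStats",
    "WindowConfig",
    "sample_stats",
    "ks_two_sample",
    "windowed_pairs",
    "pearson_windowed",
    "choose_window",
]


@dataclass(frozen=True)
class SampleStats:
    """Sample size, mean, sd (n-1 denominator) and normalized variance."""

    n: int
    mean: float
    sd: float
    normalized_variance: float  # sigma^2 / mu^2, the squared CV


def sample_stats(values: Sequence[float]) -> SampleStats:
    """Mean, standard deviation and normalized variance sigma^2/mu^2.

    A normalized variance below 1 marks a sub-Poissonian (more regular
    than exponential) duration distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return SampleStats(n=x.size, mean=mu, sd=sd,
                       normalized_variance=(sd / mu) ** 2)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Exact p-value by enumeration for samples of at most 10 each,
    otherwise the asymptotic Kolmogorov distribution with effective
    sample size ``n_a n_b / (n_a + n_b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class WindowConfig:
    """Observation window for the correlation analysis.

    ``window`` (W) is the per-cell observation span after t0; ``t_total``
    (T) the full measurement length.  Cells with ``t0 > T - W`` are
    dropped; in kept cells only productions in [t0, t0 + W] count.
    """

    window: float
    t_total: float

    def __post_init__(self) -> None:
        if not (0 < self.window <= self.t_total):
            raise ValueError("require 0 < window <= t_total")


def windowed_pairs(series: Iterable[EventSeries], config: WindowConfig,
                   pairs: str = "t0_dt") -> tuple[np.ndarray, np.ndarray]:
    """Collect (x, y) pairs after windowing.

    ``pairs="t0_dt"`` pairs each kept cell's t0 with each of its intervals
    inside the window; ``pairs="consecutive"`` pairs successive intervals
    (dt_i, dt_{i+1}) inside the window.
    """
    xs: list[float] = []
    ys: list[float] = []
    for s in series:
        if s.t0 is None or s.t0 > config.t_total - config.window:
            continue
        t = np.unique(s.production_times)
        t = t[(t >= s.t0) & (t <= s.t0 + config.window)]
        dts = np.diff(t)
        if pairs == "t0_dt":
            xs.extend([s.t0] * dts.size)
            ys.extend(dts.tolist())
        elif pairs == "consecutive":
            xs.extend(dts[:-1].tolist())
            ys.extend(dts[1:].tolist())
        else:
            raise ValueError(f"unknown pairs mode {pairs!r}")
    return np.asarray(xs), np.asarray(ys)


def choose_window(series: Sequence[EventSeries], t_total: float,
                  frame_interval: float, pairs: str = "t0_dt") -> float:
    """Scan W over the frame grid and return the W maximizing the number
    of usable pairs (largest such W on ties)."""
    n_frames = int(round(t_total / frame_interval))
    best_w = frame_interval
    best_n = -1
    for k in range(1, n_frames + 1):
        w = k * frame_interval
        n = windowed_pairs(series, WindowConfig(w, t_total), pairs)[0].size
        if n >= best_n:
            best_n, best_w = n, w
    return best_w


def pearson_windowed(series: Sequence[EventSeries], config: WindowConfig,
                     pairs: str = "t0_dt") -> tuple[float, float, int]:
    """Pearson correlation of windowed pairs with a two-sided t-test p.

    Returns ``(r, p, n_pairs)``; raises if fewer than 3 pairs survive the
    window (the error names the window so the caller can widen it).
    """
    x, y = windowed_pairs(series, config, pairs)
    if x.size < 3:
        raise ValueError(
            f"only {x.size} pairs survive window W={config.window:g} s; "
            "need >= 3 (shrink the window or add cells)")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
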