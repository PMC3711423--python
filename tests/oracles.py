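"""Independent oracles used across the test suite.

These deliberately avoid the code paths they check: brute-force
enumeration for the segmentation DP, a discretized Volterra solver for
the renewal function, and closed forms for the immigration-death
process.
"""

from __future__ import annotations

import itertools

import numpy as np


def bruteforce_partition_sse(y: np.ndarray, k: int) -> float:
    """Minimum SSE over every placement of k-1 breakpoints (unconstrained
    segment means).  Exponential in k; only for short traces."""
    T = y.size

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = np.inf
    for bps in itertools.combinations(range(1, T), k - 1):
        edges = (0,) + bps + (T,)
        total = sum(sse(y[a:b]) for a, b in zip(edges[:-1], edges[1:]))
        best = min(best, total)
    return best


def renewal_mean(pdf, cdf, t_grid: np.ndarray, h: float = 5.0) -> np.ndarray:
    """Expected event count m(t) of an ordinary renewal process by
    discretizing the renewal equation m = F + f * m (Volterra, trapezoid)."""
    t_max = float(t_grid[-1])
    n = int(np.ceil(t_max / h)) + 1
    tt = np.arange(n) * h
    f = pdf(tt)
    F = cdf(tt)
    m = np.zeros(n)
    for i in range(1, n):
        # trapezoid of f(s) m(t-s), s in [0, t]; the s=0 term contains the
        # unknown m(t) itself (implicit when f(0) > 0), so solve for it
        integrand = m[i::-1] * f[: i + 1]
        integrand[0] = 0.0
        known = np.trapezoid(integrand, dx=h)
        m[i] = (F[i] + known) / (1.0 - 0.5 * h * f[0])
    return np.interp(t_grid, tt, m)


def immigration_death_mean(k: float, kd: float, t: np.ndarray) -> np.ndarray:
    """Mean of the immigration-death process started empty: (k/kd)(1-e^-kd t)."""
    t = np.asarray(t, dtype=float)
    return (k / kd) * (1.0 - np.exp(-kd * t))
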