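"""d-step (hypoexponential) duration models and intake-time estimation.

A duration made of d sequential, independent, exponentially distributed
steps with rates lambda_1..lambda_d follows a hypoexponential (phase-type)
law with mean sum(1/lambda_i) and variance sum(1/lambda_i^2).  Both t0
(intake followed by the first initiation, d = 5) and dt (initiation
alone, d = 3) are modelled this way; the intake proper is d = 2.

Densities and CDFs are evaluated through the phase-type representation
(bidiagonal generator, matrix exponential computed by uniformization),
which stays numerically stable when rates coincide — the Erlang limit
that maximum-likelihood optimizers routinely visit.  The textbook
partial-fraction formula for distinct rates is kept only as a
cross-check; it loses all precision near equal rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HypoExpModel",
    "TdiffEstimate",
    "FitError",
    "hypoexp_pdf",
    "hypoexp_cdf",
    "hypoexp_pdf_partial_fraction",
    "fit_hypoexp",
    "ks_gof",
    "estimate_tdiff",
]


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best model found."""

    def __init__(self, message: str, best_model: "HypoExpModel | None" = None):
        super().__init__(message)
        self.best_model = best_model


@dataclass(frozen=True)
class HypoExpModel:
    """Sum of d independent exponential steps; rates sorted ascending."""

    rates: tuple[float, ...]
    loglik: float | None = None

    def __post_init__(self) -> None:
        r = tuple(sorted(float(x) for x in self.rates))
        if not r or any((not np.isfinite(x)) or x <= 0 for x in r):
            raise ValueError("rates must be nonempty, finite and > 0")
        object.__setattr__(self, "rates", r)

    @property
    def d(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(sum(1.0 / r for r in self.rates))

    @property
    def var(self) -> float:
        return float(sum(1.0 / r**2 for r in self.rates))

    @property
    def sd(self) -> float:
        return self.var**0.5

    def pdf(self, t):
        return hypoexp_pdf(self.rates, t)

    def cdf(self, t):
        return hypoexp_cdf(self.rates, t)

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        from .synthetic_data import sample_hypoexp

        return sample_hypoexp(self.rates, n, seed)


def _uniformization_terms(rates: Sequence[float], mu_max: float):
    """Coefficient sequences a_k (pdf) and b_k (survival) of the
    uniformized phase-type exponential, plus the truncation order K.

    exp(T t) = sum_k Pois(k; L t) P^k with L = max rate, P = I + T/L;
    pdf(t) = sum_k Pois_k * a_k, 1 - cdf(t) = sum_k Pois_k * b_k where
    a_k = (alpha P^k) . t_exit and b_k = (alpha P^k) . 1.
    """
    lam = np.asarray(rates, dtype=float)
    d = lam.size
    L = lam.max()
    # truncation: cover the Poisson(mu_max) mass to ~1e-13
    K = int(np.ceil(mu_max + 12.0 * np.sqrt(mu_max + 1.0) + 25.0))
    v = np.zeros(d)
    v[0] = 1.0
    a = np.empty(K + 1)
    b = np.empty(K + 1)
    p_stay = 1.0 - lam / L
    p_move = lam / L
    for k in range(K + 1):
        a[k] = v[-1] * lam[-1]
        b[k] = v.sum()
        nxt = v * p_stay
        nxt[1:] += v[:-1] * p_move[:-1]
        v = nxt
    return L, a, b, K


_MAX_TERMS = 200_000


def _phase_type_eval(rates: Sequence[float], t, want_pdf: bool) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros(t.shape)
    pos = t > 0
    if pos.any():
        tp = t[pos]
        L_mu = float(np.max(rates) * tp.max())
        if L_mu > _MAX_TERMS:
            raise ValueError("rate*t too large for stable series evaluation")
        L, a, b, K = _uniformization_terms(rates, L_mu)
        k = np.arange(K + 1)
        pois = stats.poisson.pmf(k[None, :], (L * tp)[:, None])
        if want_pdf:
            out[pos] = pois @ a
        else:
            out[pos] = 1.0 - pois @ b
    if want_pdf and len(rates) == 1:
        out[t == 0] = rates[0]  # single-step density is discontinuous at 0
    out = np.clip(out, 0.0, None)
    return out[0] if scalar else out


def hypoexp_pdf(rates: Sequence[float], t) -> np.ndarray:
    """Density of the sum of independent exponentials (0 for t < 0)."""
    return _phase_type_eval(tuple(rates), t, want_pdf=True)


def hypoexp_cdf(rates: Sequence[float], t) -> np.ndarray:
    """CDF of the sum of independent exponentials."""
    return np.clip(_phase_type_eval(tuple(rates), t, want_pdf=False), 0.0, 1.0)


def hypoexp_pdf_partial_fraction(rates: Sequence[float], t) -> np.ndarray:
    """Distinct-rate closed form sum_i w_i lambda_i exp(-lambda_i t).

    Catastrophically cancels when rates nearly coincide; provided as an
    independent cross-check of the phase-type evaluation, not for use in
    fitting.
    """
    lam = np.asarray(rates, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w = np.ones(lam.size)
    for i in range(lam.size):
        for j in range(lam.size):
            if i != j:
                w[i] *= lam[j] / (lam[j] - lam[i])
    out = np.where(t < 0, 0.0, (w * lam * np.exp(-np.outer(t, lam))).sum(axis=1))
    return out


def _nll(log_rates: np.ndarray, x: np.ndarray) -> float:
    f = hypoexp_pdf(np.exp(log_rates), x)
    return -float(np.sum(np.log(np.clip(f, 1e-300, None))))


def fit_hypoexp(samples: Sequence[float], d: int, n_starts: int = 6,
                seed: int = 0) -> HypoExpModel:
    """Maximum-likelihood d-step model for a sample of durations.

    Multi-start bounded optimization over log rates; starts are the
    moment-matched Erlang point (all rates d/mean) and seeded lognormal
    perturbations of it.  Rates are returned sorted ascending (the
    likelihood is permutation-invariant).

    Requires ``n >= 10 d`` strictly positive samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10 * d:
        raise ValueError(f"need at least {10 * d} samples for d={d}")
    if (x <= 0).any():
        raise ValueError("samples must be > 0")
    if d == 1:
        rate = 1.0 / float(x.mean())
        ll = float(np.sum(np.log(rate) - rate * x))
        return HypoExpModel(rates=(rate,), loglik=ll)

    mean = float(x.mean())
    lo, hi = np.log(1.0 / (100.0 * d * mean)), np.log(100.0 * d / mean)
    bounds = [(lo, hi)] * d
    rng = np.random.default_rng(seed)
    base = np.full(d, np.log(d / mean))
    starts = [base]
    # a spread start helps when the sample CV exceeds the Erlang 1/sqrt(d)
    starts.append(base + np.linspace(-1.0, 1.0, d))
    while len(starts) < n_starts:
        starts.append(base + rng.normal(0.0, 0.7, size=d))

    best = None
    for s0 in starts:
        try:
            res = optimize.minimize(_nll, np.clip(s0, lo, hi), args=(x,),
                                    method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("no optimizer start converged", None)
    model = HypoExpModel(rates=tuple(np.exp(best.x)), loglik=-float(best.fun))
    if not best.success and best.fun > _nll(np.log(model.rates), x) + 1e-6:
        raise FitError("optimization did not converge", model)
    return model


def ks_gof(samples: Sequence[float], model: HypoExpModel,
           bootstrap: int = 0, seed: int = 0) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of samples against a model CDF.

    Default p-value is the standard (asymptotic for large n, exact for
    small n) distribution of D under a fully specified model.  With
    ``bootstrap > 0`` a parametric bootstrap p-value is returned instead:
    the model is resampled and refit ``bootstrap`` times, which accounts
    for the parameters having been estimated from the same data.
    """
    x = np.asarray(samples, dtype=float)
    res = stats.kstest(x, model.cdf)
    d_obs = float(res.statistic)
    if bootstrap <= 0:
        return d_obs, float(res.pvalue)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(bootstrap):
        xb = model.sample(x.size, rng)
        mb = fit_hypoexp(xb, model.d, seed=int(rng.integers(2**31)))
        db = stats.kstest(xb, mb.cdf).statistic
        exceed += db >= d_obs
    return d_obs, (1.0 + exceed) / (bootstrap + 1.0)


@dataclass(frozen=True)
class TdiffEstimate:
    """Moments of the intake time obtained by moment subtraction."""

    mean: float
    sd: float
    valid: bool


def estimate_tdiff(stats_t0, stats_dt) -> TdiffEstimate:
    """Estimate intake-time moments by subtracting dt moments from t0.

    t0 is intake plus one initiation interval; assuming the two are
    independent, the intake mean is ``mu_t0 - mu_dt`` and its variance
    ``sd_t0^2 - sd_dt^2``.  A negative variance difference (independence
    violated or sampling noise) yields ``valid=False`` with ``sd = nan``
    rather than an exception — the mean subtraction needs no independence
    and is always reported.
    """
    mean = stats_t0.mean - stats_dt.mean
    var = stats_t0.sd**2 - stats_dt.sd**2
    if var >= 0:
        return TdiffEstimate(mean=mean, sd=float(np.sqrt(var)), valid=True)
    return TdiffEstimate(mean=mean, sd=float("nan"), valid=False)
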