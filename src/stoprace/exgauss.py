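"""Numerically stable ex-Gaussian distribution primitives.

The ex-Gaussian is the convolution of a Normal(mu, sigma) with an
Exponential distribution of mean tau.  It is the standard descriptive model
for unimodal, positively skewed response-time data: mu and sigma capture the
leading edge and mode, tau the slow tail.  Its mean is ``mu + tau`` and its
variance ``sigma**2 + tau**2``.

The naive density formula contains the factor ``exp(sigma**2 / (2 tau**2))``
which overflows whenever tau is small relative to sigma, so every function
here works in log space.  Two algebraically equivalent forms of the
log-density are switched on the sign of ``z = (t - mu)/sigma - sigma/tau``:

* ``z >= 0`` — the direct form with ``scipy.special.log_ndtr``; the large
  positive exponent is cancelled analytically by the Gaussian tail term.
* ``z < 0`` — a form based on the scaled complementary error function
  ``erfcx``, which has no large intermediate at all.

The survivor function uses the identity ``S(t) = Phi(-(t-mu)/sigma)
+ tau * f(t)``, a sum of two positive stable terms, combined with
``logaddexp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "ExGaussParams",
    "exg_logpdf",
    "exg_pdf",
    "exg_logsf",
    "exg_sf",
    "exg_cdf",
    "exg_mean",
    "exg_var",
    "exg_rand",
]

_LOG_HALF = float(np.log(0.5))
_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters (mu, sigma, tau) of one ex-Gaussian finishing-time law.

    mu, sigma are the mean and SD of the Gaussian component, tau the mean of
    the exponential component, all in the time unit of the data (the package
    is unit-agnostic; default priors elsewhere assume milliseconds).
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        _check_params(self.sigma, self.tau)

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma**2 + self.tau**2

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.sigma, self.tau)


def _check_params(sigma: float, tau: float) -> None:
    if not (sigma > 0.0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not (tau > 0.0):
        raise ValueError(f"tau must be > 0, got {tau}")


def _logpdf(t, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Log-density, array-valued, no parameter validation (hot path)."""
    t = np.asarray(t, dtype=float)
    u = (t - mu) / sigma
    k = sigma / tau
    z = u - k
    out = np.empty(z.shape, dtype=float)
    neg = z < 0.0
    if neg.any():
        # exact rewrite: log f = -log tau + log(1/2) - u^2/2 + log erfcx(-z/sqrt2)
        out[neg] = (
            -np.log(tau)
            + _LOG_HALF
            - 0.5 * u[neg] ** 2
            + np.log(special.erfcx(-z[neg] / _SQRT2))
        )
    pos = ~neg
    if pos.any():
        out[pos] = (
            -np.log(tau)
            + (mu - t[pos]) / tau
            + 0.5 * k * k
            + special.log_ndtr(z[pos])
        )
    return out


def _logsf(t, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Log survivor log(1 - CDF), array-valued, stable in both tails."""
    t = np.asarray(t, dtype=float)
    u = (t - mu) / sigma
    # S(t) = Phi(-u) + tau * f(t): both addends positive, no cancellation.
    a = special.log_ndtr(-u)
    b = np.log(tau) + _logpdf(t, mu, sigma, tau)
    out = np.logaddexp(a, b)
    return np.minimum(out, 0.0)


def _rand(mu: float, sigma: float, tau: float, n: int, rng: np.random.Generator):
    return rng.normal(mu, sigma, size=n) + rng.exponential(tau, size=n)


def _as_result(x: np.ndarray, scalar: bool):
    return float(x[()]) if scalar else x


def _prep(t):
    scalar = np.ndim(t) == 0
    return np.atleast_1d(np.asarray(t, dtype=float)), scalar


def exg_logpdf(t, p: ExGaussParams):
    """Log of the ex-Gaussian density at ``t`` (scalar or array)."""
    tt, scalar = _prep(t)
    out = _logpdf(tt, p.mu, p.sigma, p.tau)
    return _as_result(out if not scalar else out[:1].reshape(()), scalar)


def exg_pdf(t, p: ExGaussParams):
    """Ex-Gaussian density at ``t``."""
    tt, scalar = _prep(t)
    out = np.exp(_logpdf(tt, p.mu, p.sigma, p.tau))
    return _as_result(out if not scalar else out[:1].reshape(()), scalar)


def exg_logsf(t, p: ExGaussParams):
    """Log survivor function log P(T > t), cancellation-free in the tails."""
    tt, scalar = _prep(t)
    out = _logsf(tt, p.mu, p.sigma, p.tau)
    return _as_result(out if not scalar else out[:1].reshape(()), scalar)


def exg_sf(t, p: ExGaussParams):
    """Survivor function P(T > t)."""
    tt, scalar = _prep(t)
    out = np.exp(_logsf(tt, p.mu, p.sigma, p.tau))
    return _as_result(out if not scalar else out[:1].reshape(()), scalar)


def exg_cdf(t, p: ExGaussParams):
    """CDF P(T <= t), computed as ``-expm1(logsf)`` for stability."""
    tt, scalar = _prep(t)
    out = -np.expm1(_logsf(tt, p.mu, p.sigma, p.tau))
    return _as_result(out if not scalar else out[:1].reshape(()), scalar)


def exg_mean(p: ExGaussParams) -> float:
    """Distribution mean, exactly ``mu + tau``."""
    return p.mu + p.tau


def exg_var(p: ExGaussParams) -> float:
    """Distribution variance, exactly ``sigma**2 + tau**2``."""
    return p.sigma**2 + p.tau**2


def exg_rand(p: ExGaussParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` variates as Normal(mu, sigma) + Exponential(tau).

    Support is the whole real line; negative draws are possible for extreme
    parameters and are the caller's concern (the trial simulator rejects
    them, the likelihood does not need to).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _rand(p.mu, p.sigma, p.tau, int(n), rng)
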