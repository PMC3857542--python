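"""Independent numerical oracles used by the test-suite.

These deliberately avoid the package's own log-space algebra: the density
oracle integrates the defining Normal x Exponential convolution directly,
the survivor oracle integrates the density oracle's tail, and the R-hat
oracle transcribes the textbook between/within-variance formula.
"""

import numpy as np
from scipy import integrate, stats


def pdf_conv_oracle(t: float, mu: float, sigma: float, tau: float) -> float:
    """Brute-force convolution quadrature of Normal(mu, sigma) x Exp(tau)."""

    def integrand(x):
        return stats.norm.pdf(x, mu, sigma) * stats.expon.pdf(t - x, scale=tau)

    lo = mu - 10.0 * sigma
    hi = min(t, mu + 10.0 * sigma)
    if hi <= lo:
        return 0.0
    val, _ = integrate.quad(integrand, lo, hi, limit=300)
    return val


def sf_tail_oracle(t: float, mu: float, sigma: float, tau: float) -> float:
    """Survivor value by integrating the convolution oracle over [t, inf)."""
    hi = mu + 12.0 * sigma + 60.0 * tau
    val, _ = integrate.quad(
        lambda u: pdf_conv_oracle(u, mu, sigma, tau), t, hi, limit=300
    )
    return val


def rhat_oracle(chains) -> float:
    """Textbook Gelman-Rubin potential scale reduction factor."""
    arrs = [np.asarray(c, dtype=float) for c in chains]
    n = arrs[0].size
    chain_means = [float(np.mean(a)) for a in arrs]
    w = float(np.mean([np.var(a, ddof=1) for a in arrs]))
    b = n * float(np.var(chain_means, ddof=1))
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))
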