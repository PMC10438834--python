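"""Beta-binomial probability math and compositional link functions.

The Beta-binomial is parameterized here by its mean ``pi`` (the mean of the
latent Beta distribution) and its concentration ``sigma`` (the sum alpha+beta
of the latent Beta shapes).  Concentration is the reciprocal notion of
variability: large ``sigma`` means proportions tightly concentrated around
``pi`` (in the limit sigma -> inf the distribution is Binomial(n, pi)), while
``sigma`` near zero pushes mass toward the extremes 0 and n.

The compositional link maps a zero-sum vector of group-level linear
predictors onto the simplex via the softmax (inverse multinomial-logistic)
function; its exact inverse on the zero-sum subspace is the centered
log-ratio (CLR).

All probability mass computations are carried out in log space via log-Beta
(log-Gamma) functions, never via raw factorials, so they remain finite for
totals well beyond 1e6.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "mean_conc_to_shapes",
    "shapes_to_mean_conc",
    "betabinom_logpmf",
    "betabinom_trunc_logpmf",
    "betabinom_rvs",
    "inv_multinomial_logistic",
    "clr",
]


def mean_conc_to_shapes(pi, sigma):
    """Convert (mean, concentration) to the Beta shape parameters.

    Parameters
    ----------
    pi : float or array
        Beta mean, strictly inside (0, 1).
    sigma : float or array
        Concentration alpha + beta, strictly positive.

    Returns
    -------
    (alpha, beta) : tuple of arrays
        ``alpha = pi * sigma`` and ``beta = (1 - pi) * sigma``.
    """
    pi = np.asarray(pi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any((pi <= 0.0) | (pi >= 1.0)):
        raise ValueError("pi must lie strictly inside (0, 1)")
    if np.any(sigma <= 0.0):
        raise ValueError("sigma must be strictly positive")
    return pi * sigma, (1.0 - pi) * sigma


def shapes_to_mean_conc(alpha, beta):
    """Inverse of :func:`mean_conc_to_shapes`; exact round-trip."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("alpha and beta must be strictly positive")
    sigma = alpha + beta
    return alpha / sigma, sigma


def _logpmf_from_shapes(k, n, alpha, beta):
    # log C(n, k) + logB(k+a, n-k+b) - logB(a, b); all terms via log-Gamma.
    log_binom = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return log_binom + betaln(k + alpha, n - k + beta) - betaln(alpha, beta)


def betabinom_logpmf(k, n, pi, sigma):
    """Log pmf of the Beta-binomial in the (mean, concentration) form.

    Broadcasts over all arguments.  Raises for counts outside ``[0, n]``.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts k must satisfy 0 <= k <= n")
    alpha, beta = mean_conc_to_shapes(pi, sigma)
    return _logpmf_from_shapes(k, n, alpha, beta)


def betabinom_trunc_logpmf(k, n, pi, sigma, lo, hi):
    """Log pmf of the Beta-binomial conditioned on ``k in [lo, hi]``.

    Used for censoring-adjusted refits after outlier removal: an observation
    retained inside a posterior-predictive interval [lo, hi] is modelled as a
    draw from the Beta-binomial truncated to that window.  The normalizer is
    a stable log-sum-exp over the (integer) support window.
    """
    lo = int(lo)
    hi = int(hi)
    n_i = int(n)
    lo = max(lo, 0)
    hi = min(hi, n_i)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside truncation window [{lo}, {hi}]")
    base = betabinom_logpmf(k, n, pi, sigma)
    if lo == 0 and hi == n_i:
        return float(base)
    support = np.arange(lo, hi + 1, dtype=float)
    log_z = logsumexp(betabinom_logpmf(support, float(n_i), pi, sigma))
    if not np.isfinite(log_z):
        raise ValueError("zero probability mass in the truncation window")
    return float(base - log_z)


def betabinom_rvs(n, pi, sigma, rng, size=None):
    """Draw Beta-binomial variates by compounding Beta and Binomial draws."""
    alpha, beta = mean_conc_to_shapes(pi, sigma)
    p = rng.beta(np.broadcast_to(alpha, size) if size is not None else alpha,
                 np.broadcast_to(beta, size) if size is not None else beta)
    return rng.binomial(np.asarray(n, dtype=np.int64), p)


def inv_multinomial_logistic(mu, axis=-1):
    """Softmax: map linear predictors to the simplex, max-subtracted."""
    mu = np.asarray(mu, dtype=float)
    shifted = mu - np.max(mu, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def clr(pi, axis=-1):
    """Centered log-ratio: log of each proportion over their geometric mean.

    Exact inverse of :func:`inv_multinomial_logistic` restricted to the
    zero-sum subspace; requires strictly positive components.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("clr requires strictly positive components")
    log_pi = np.log(pi)
    return log_pi - np.mean(log_pi, axis=axis, keepdims=True)
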