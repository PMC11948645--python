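"""Sinh-arcsinh (SHASH) distribution.

Four-parameter location/scale/skewness/tail family used as the response
distribution of the normative growth models. With location ``mu``, scale
``sigma > 0``, skewness ``nu`` and tail weight ``tau > 0`` the CDF is

    F(y) = Phi( sinh( tau * asinh((y - mu)/sigma) - nu ) )

where Phi is the standard normal CDF. At ``nu = 0, tau = 1`` the family
reduces exactly to the Gaussian N(mu, sigma^2); ``nu`` tilts the skew
(positive nu -> right skew) and ``tau`` controls tail weight (tau > 1
lighter than Gaussian, tau < 1 heavier).

All functions broadcast over ``y`` and the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri


@dataclass(frozen=True)
class ShashParams:
    """Parameter bundle; validates the positivity constraints."""

    mu: float
    sigma: float
    nu: float
    tau: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.sigma) > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not np.all(np.asarray(self.tau) > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")


def _unpack(params):
    if isinstance(params, ShashParams):
        return params.mu, params.sigma, params.nu, params.tau
    mu, sigma, nu, tau = params
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be > 0")
    if not np.all(np.asarray(tau) > 0):
        raise ValueError("tau must be > 0")
    return mu, sigma, nu, tau


def shash_cdf(y, params):
    """F(y) = Phi(sinh(tau * asinh(z) - nu)), z = (y - mu)/sigma."""
    mu, sigma, nu, tau = _unpack(params)
    z = (np.asarray(y, dtype=float) - mu) / sigma
    r = np.sinh(tau * np.arcsinh(z) - nu)
    return ndtr(r)


def shash_logpdf(y, params):
    mu, sigma, nu, tau = _unpack(params)
    z = (np.asarray(y, dtype=float) - mu) / sigma
    u = tau * np.arcsinh(z) - nu
    r = np.sinh(u)
    # log |dr/dy| = log(tau) + log cosh(u) - log sigma - 0.5 log(1 + z^2)
    return (
        -0.5 * r**2
        - 0.5 * np.log(2.0 * np.pi)
        + np.log(tau)
        + _logcosh(u)
        - np.log(sigma)
        - 0.5 * np.log1p(z**2)
    )


def shash_pdf(y, params):
    return np.exp(shash_logpdf(y, params))


def shash_logcdf(y, params):
    mu, sigma, nu, tau = _unpack(params)
    z = (np.asarray(y, dtype=float) - mu) / sigma
    return log_ndtr(np.sinh(tau * np.arcsinh(z) - nu))


def shash_quantile(p, params):
    """Exact inverse of :func:`shash_cdf`."""
    mu, sigma, nu, tau = _unpack(params)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must be strictly inside (0, 1)")
    r = ndtri(p)
    return mu + sigma * np.sinh((np.arcsinh(r) + nu) / tau)


def shash_median(params):
    """Closed form median: mu + sigma * sinh(nu / tau)."""
    mu, sigma, nu, tau = _unpack(params)
    return mu + sigma * np.sinh(nu / tau)


def shash_rvs(params, size=None, rng=None):
    """Draw samples by inverse-transform of standard normal variates."""
    mu, sigma, nu, tau = _unpack(params)
    rng = np.random.default_rng(rng)
    if size is None:
        size = np.broadcast(mu, sigma, nu, tau).shape or None
    r = rng.standard_normal(size)
    return mu + sigma * np.sinh((np.arcsinh(r) + nu) / tau)


def _logcosh(x):
    x = np.asarray(x, dtype=float)
    return np.abs(x) + np.log1p(np.exp(-2.0 * np.abs(x))) - np.log(2.0)
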