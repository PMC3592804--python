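"""Fractional-polynomial curve primitives and error-family log densities.

The one-compartment model with first-order absorption,

    c(t) = D*ka / (V*(ka - ke)) * (exp(-ke*t) - exp(-ka*t)),

rises then falls in t.  On the log scale it is well approximated by a
fractional polynomial in time,

    log c(t) = beta0 + beta1 * t**p1 + beta2 * t**p2,

with default powers (1, -1), i.e. log c = beta0 + beta1*t + beta2/t.
With beta1 < 0 and beta2 < 0 this basis gives an increasing absorption
phase followed by a decreasing elimination phase, mirroring the
compartmental curve.

Residual error families supported on top of that mean:

* isotropic multivariate normal (one variance per observation vector),
* isotropic multivariate Student t (one scatter element, shared
  degrees of freedom; heavy tails make the fit robust to outliers),
* gamma with log link (used for model comparison against the
  gamma-GLM tradition).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .exceptions import PKDomainError

__all__ = [
    "build_design_matrix",
    "linear_predictor",
    "one_compartment_conc",
    "mvt_logpdf",
    "mvn_logpdf",
    "gamma_loglik_loglink",
]


def build_design_matrix(times, powers=(1.0, -1.0)):
    """Design matrix of the log-linear fractional-polynomial model.

    Row j is ``(1, t_j**p1, t_j**p2)``; with the default powers
    ``(1, -1)`` this is ``(1, t_j, 1/t_j)``.

    Parameters
    ----------
    times : array_like
        Sampling times in hours, all strictly positive (the ``t**-1``
        basis term diverges at zero).
    powers : tuple of float
        The two fractional-polynomial exponents ``(p1, p2)``; must differ.

    Returns
    -------
    ndarray of shape (n, 3)
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise PKDomainError("times must be one-dimensional")
    bad = np.flatnonzero(~(t > 0))
    if bad.size:
        raise PKDomainError(
            f"non-positive time {t[bad[0]]!r} at index {bad[0]}"
        )
    p1, p2 = powers
    if p1 == p2:
        raise PKDomainError("fractional-polynomial powers must differ")
    return np.column_stack([np.ones_like(t), t ** p1, t ** p2])


def linear_predictor(X, beta, b=0.0, offset=0.0):
    """Modelled log-concentration mean ``X @ beta + b + offset``.

    ``b`` is the subject random intercept, ``offset`` an optional fixed
    shift (e.g. log-dose); both broadcast over observations.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise PKDomainError(
            f"design matrix has {X.shape} shape; incompatible with "
            f"beta of length {beta.shape[0]}"
        )
    return X @ beta + b + offset


def one_compartment_conc(D, V, ka, ke, t):
    """One-compartment concentration with first-order absorption.

    ``c(t) = D*ka / (V*(ka - ke)) * (exp(-ke*t) - exp(-ka*t))``

    Parameters
    ----------
    D : float
        Dose (mass).
    V : float
        Apparent volume of distribution (> 0).
    ka, ke : float
        Absorption and elimination rate constants (1/h); ``ka > 0``,
        ``ke >= 0`` and ``ka != ke`` (the coincident-rate limit is
        rejected rather than special-cased).
    t : array_like
        Times (h), non-negative.
    """
    if V <= 0:
        raise PKDomainError("volume V must be positive")
    if ka <= 0 or ke < 0:
        raise PKDomainError("require ka > 0 and ke >= 0")
    if ka == ke:
        raise PKDomainError("degenerate case ka == ke is not supported")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise PKDomainError("times must be non-negative")
    return D * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def _as_pair(y, mu):
    y = np.atleast_1d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    return y, mu


def mvt_logpdf(y, mu, scatter, nu):
    """Log density of an isotropic multivariate Student t.

    The scatter matrix is ``scatter * I`` (a single positive element);
    for nu > 2 the implied per-coordinate variance is
    ``scatter * nu / (nu - 2)``.  As nu -> inf the density tends to the
    isotropic normal with variance ``scatter``.
    """
    if scatter <= 0:
        raise PKDomainError("scatter must be positive")
    if nu <= 0:
        raise PKDomainError("degrees of freedom must be positive")
    y, mu = _as_pair(y, mu)
    n = y.size
    delta = np.sum((y - mu) ** 2) / scatter
    return float(
        gammaln((nu + n) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * n * np.log(nu * np.pi)
        - 0.5 * n * np.log(scatter)
        - 0.5 * (nu + n) * np.log1p(delta / nu)
    )


def mvn_logpdf(y, mu, variance):
    """Log density of an isotropic multivariate normal with variance*I."""
    if variance <= 0:
        raise PKDomainError("variance must be positive")
    y, mu = _as_pair(y, mu)
    n = y.size
    rss = np.sum((y - mu) ** 2)
    return float(-0.5 * n * np.log(2.0 * np.pi * variance) - 0.5 * rss / variance)


def gamma_loglik_loglink(y, eta, shape):
    """Gamma log likelihood with log link.

    Observation j has mean ``exp(eta_j)`` and shape ``a`` (so variance
    ``mean**2 / a``); density
    ``a**a / Gamma(a) * y**(a-1) * mu**-a * exp(-a*y/mu)``.
    Returns the sum over observations.
    """
    if shape <= 0:
        raise PKDomainError("gamma shape must be positive")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    eta = np.broadcast_to(np.asarray(eta, dtype=float), y.shape)
    if np.any(y <= 0):
        raise PKDomainError("gamma-family observations must be positive")
    a = shape
    return float(
        np.sum(
            a * np.log(a)
            - gammaln(a)
            + (a - 1.0) * np.log(y)
            - a * eta
            - a * y * np.exp(-eta)
        )
    )
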