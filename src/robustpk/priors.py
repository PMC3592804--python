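"""Prior specification and log-prior evaluation.

Independent priors: normal on each fixed effect (diagonal prior
covariance), gamma — or optionally inverse-gamma — on the two variance
components, and the second-stage normal N(0, sigma1) on each subject
random intercept.  Defaults are diffuse: beta variance 100 per
component, variance-component shape and rate 0.01.

The prior mean of beta defaults to the conventional initial estimate
(0.1, -0.1, -0.1); with variance 100 it is effectively flat over the
constrained region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import gammaln

from .exceptions import PKDomainError
from .model import ParameterState

__all__ = ["PriorSpec", "log_prior"]

VARIANCE_PRIOR_FAMILIES = ("gamma", "invgamma")


@dataclass(frozen=True)
class PriorSpec:
    beta_mean: Tuple[float, float, float] = (0.1, -0.1, -0.1)
    beta_var: Tuple[float, float, float] = (100.0, 100.0, 100.0)
    sigma1_shape: float = 0.01
    sigma1_rate: float = 0.01
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01
    variance_prior: str = "gamma"

    def __post_init__(self):
        if any(v <= 0 for v in self.beta_var):
            raise PKDomainError("prior variances must be positive")
        for v in (self.sigma1_shape, self.sigma1_rate,
                  self.sigma2_shape, self.sigma2_rate):
            if v <= 0:
                raise PKDomainError("variance-prior shapes/rates must be positive")
        if self.variance_prior not in VARIANCE_PRIOR_FAMILIES:
            raise PKDomainError(
                f"variance_prior must be one of {VARIANCE_PRIOR_FAMILIES}"
            )


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return (shape * np.log(rate) - gammaln(shape)
            + (shape - 1.0) * np.log(x) - rate * x)


def _invgamma_logpdf(x: float, shape: float, rate: float) -> float:
    return (shape * np.log(rate) - gammaln(shape)
            - (shape + 1.0) * np.log(x) - rate / x)


def variance_logprior(x: float, shape: float, rate: float,
                      family: str = "gamma") -> float:
    """Log prior density of one variance component."""
    if x <= 0:
        raise PKDomainError("variance component must be positive")
    if family == "gamma":
        return float(_gamma_logpdf(x, shape, rate))
    return float(_invgamma_logpdf(x, shape, rate))


def log_prior(state: ParameterState, priors: PriorSpec) -> float:
    """Joint log prior: beta normals + variance-component densities +
    the second-stage N(0, sigma1) terms for the random intercepts."""
    mu = np.asarray(priors.beta_mean, dtype=float)
    var = np.asarray(priors.beta_var, dtype=float)
    lp = float(
        np.sum(-0.5 * np.log(2.0 * np.pi * var)
               - 0.5 * (state.beta - mu) ** 2 / var)
    )
    lp += variance_logprior(state.sigma1, priors.sigma1_shape,
                            priors.sigma1_rate, priors.variance_prior)
    lp += variance_logprior(state.sigma2, priors.sigma2_shape,
                            priors.sigma2_rate, priors.variance_prior)
    m = state.b.size
    lp += float(
        -0.5 * m * np.log(2.0 * np.pi * state.sigma1)
        - 0.5 * np.sum(state.b ** 2) / state.sigma1
    )
    return lp
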