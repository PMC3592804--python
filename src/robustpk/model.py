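"""Model specification, parameter state, likelihoods, and the user-facing
Model/Results pair.

The hierarchy is a two-stage generalized linear mixed model on the log
scale.  Stage one: for subject i with design matrix X_i (fractional
polynomial in time) and scalar random intercept b_i,

    log y_i | b_i  ~  family(X_i beta + b_i 1 + offset, sigma2, [nu]) ,

where family is an isotropic multivariate normal (variance sigma2) or
multivariate Student t (scatter sigma2, degrees of freedom nu), or a
gamma GLM with log link on the raw concentrations (shape parameter,
used for model comparison).  Stage two: b_i ~ N(0, sigma1).

Sign constraints beta1 < 0 and beta2 < 0 keep the fitted curve rising
then falling, as the one-compartment model requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import (
    build_design_matrix,
    gamma_loglik_loglink,
    linear_predictor,
    mvn_logpdf,
    mvt_logpdf,
)
from .data import PKDataset
from .exceptions import DataValidationError, PKDomainError

__all__ = [
    "ModelSpec",
    "ParameterState",
    "conditional_loglik",
    "marginal_normal_loglik",
    "PKMixedModel",
    "PKMixedResults",
]

ERROR_FAMILIES = ("normal", "t", "gamma")


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices: basis powers, error family, and family knobs.

    Parameters
    ----------
    powers : (p1, p2)
        Fractional-polynomial exponents; default ``(1, -1)`` gives
        ``log c = beta0 + beta1*t + beta2/t``.
    error_family : {"normal", "t", "gamma"}
    nu : float
        Degrees of freedom of the t family (> 2 so the scatter is
        finite-variance); ignored by the other families.
    dose_offset : bool
        If true, add ``log(dose)`` as a fixed-coefficient offset to the
        linear predictor (for heterogeneous doses); by default a common
        dose is absorbed into beta0.
    gamma_shape : float, optional
        Shape of the gamma family (required when fitting it).
    """

    powers: Tuple[float, float] = (1.0, -1.0)
    error_family: str = "t"
    nu: float = 4.0
    dose_offset: bool = False
    gamma_shape: Optional[float] = None

    def __post_init__(self):
        if self.error_family not in ERROR_FAMILIES:
            raise PKDomainError(
                f"unknown error family {self.error_family!r}; "
                f"choose one of {ERROR_FAMILIES}"
            )
        p1, p2 = self.powers
        if p1 == p2:
            raise PKDomainError("powers p1 and p2 must differ")
        if self.error_family == "t" and not self.nu > 2:
            raise PKDomainError("t family requires nu > 2")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise PKDomainError("gamma_shape must be positive")

    def offset_for(self, dose: float) -> float:
        return float(np.log(dose)) if self.dose_offset else 0.0


@dataclass(frozen=True)
class ParameterState:
    """One point in parameter space: fixed effects, random effects, variances."""

    beta: np.ndarray
    b: np.ndarray
    sigma1: float
    sigma2: float

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "b", b)
        if beta.shape != (3,):
            raise PKDomainError("beta must be a triple (beta0, beta1, beta2)")
        if not np.all(np.isfinite(beta)):
            raise PKDomainError("beta must be finite")
        if not (beta[1] < 0 and beta[2] < 0):
            raise PKDomainError(
                "constraint violated: beta1 < 0 and beta2 < 0 are required "
                "for an increasing absorption / decreasing elimination curve"
            )
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise PKDomainError("sigma1 and sigma2 must be positive")

    @property
    def n_subjects(self) -> int:
        return self.b.size

    def replace(self, **kw) -> "ParameterState":
        return replace(self, **kw)


def _subject_offset(spec: ModelSpec, block) -> float:
    return spec.offset_for(block.dose)


def conditional_loglik(data: PKDataset, state: ParameterState,
                       spec: ModelSpec) -> float:
    """First-stage log likelihood given the random effects.

    For the normal and t families the density is evaluated on the log
    concentrations; for the gamma family on the raw concentrations with
    the linear predictor as log mean.
    """
    if state.b.size != data.n_subjects:
        raise PKDomainError(
            f"state has {state.b.size} random effects for "
            f"{data.n_subjects} subjects"
        )
    if spec.error_family == "gamma" and spec.gamma_shape is None:
        raise PKDomainError("gamma family requires spec.gamma_shape")
    total = 0.0
    for i, block in enumerate(data):
        X = build_design_matrix(block.times, spec.powers)
        eta = linear_predictor(X, state.beta, state.b[i],
                               _subject_offset(spec, block))
        if spec.error_family == "normal":
            total += mvn_logpdf(block.log_conc, eta, state.sigma2)
        elif spec.error_family == "t":
            total += mvt_logpdf(block.log_conc, eta, state.sigma2, spec.nu)
        else:
            total += gamma_loglik_loglink(block.concentrations, eta,
                                          spec.gamma_shape)
    return total


def marginal_normal_loglik(data: PKDataset, beta, sigma1: float,
                           sigma2: float, spec: ModelSpec) -> float:
    """Random effects integrated out analytically (normal family only).

    With b_i ~ N(0, sigma1) and isotropic normal errors the marginal of
    the log concentrations is multivariate normal with compound-symmetric
    covariance ``sigma2*I + sigma1*J``; the Sherman-Morrison identity
    gives the quadratic form and determinant in closed form.
    """
    if spec.error_family != "normal":
        raise PKDomainError("closed-form marginal exists for the normal family")
    if sigma1 < 0 or sigma2 <= 0:
        raise PKDomainError("require sigma1 >= 0 and sigma2 > 0")
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for block in data:
        X = build_design_matrix(block.times, spec.powers)
        r = block.log_conc - linear_predictor(X, beta, 0.0,
                                              _subject_offset(spec, block))
        n = r.size
        s = float(np.sum(r))
        rss = float(np.sum(r * r))
        logdet = (n - 1) * np.log(sigma2) + np.log(sigma2 + n * sigma1)
        quad = rss / sigma2 - sigma1 * s * s / (sigma2 * (sigma2 + n * sigma1))
        total += -0.5 * n * np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * quad
    return total


class PKMixedModel:
    """Bayesian population-PK mixed model on concentration-time data.

    Parameters
    ----------
    data : PKDataset
    spec : ModelSpec, optional
        Defaults to the t family with nu = 4 and powers (1, -1).
    priors : PriorSpec, optional
        Defaults to diffuse independent priors (normal for beta, gamma
        for the variance components).

    Examples
    --------
    >>> from robustpk import PKMixedModel, preset_example, simulate_dataset
    >>> data, truth = simulate_dataset(preset_example(1))
    >>> res = PKMixedModel(data).fit(n_iter=2000, burn_in=1500, seed=1)
    >>> res.params["beta0"]  # doctest: +SKIP
    """

    def __init__(self, data: PKDataset, spec: Optional[ModelSpec] = None,
                 priors=None):
        if not isinstance(data, PKDataset):
            raise DataValidationError("data must be a PKDataset")
        self.data = data
        self.spec = spec if spec is not None else ModelSpec()
        if priors is None:
            from .priors import PriorSpec

            priors = PriorSpec()
        self.priors = priors

    @classmethod
    def from_dataframe(cls, df, spec: Optional[ModelSpec] = None, priors=None):
        return cls(PKDataset.from_dataframe(df), spec=spec, priors=priors)

    @classmethod
    def from_csv(cls, path, spec: Optional[ModelSpec] = None, priors=None):
        from .data import read_pk_csv

        return cls(read_pk_csv(path), spec=spec, priors=priors)

    def loglike(self, state: ParameterState) -> float:
        """Conditional (stage-one) log likelihood at ``state``."""
        return conditional_loglik(self.data, state, self.spec)

    def logposterior(self, state: ParameterState) -> float:
        from .sampler import log_posterior

        return log_posterior(state, self.data, self.spec, self.priors)

    def fit(self, config=None, **kwargs) -> "PKMixedResults":
        """Run the constrained Metropolis-Hastings sampler.

        Either pass an :class:`~robustpk.sampler.MCMCConfig` or keyword
        fields for one (``n_iter``, ``burn_in``, ``seed``, ...).
        """
        from .sampler import MCMCConfig, run_chain

        if config is None:
            config = MCMCConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        chain = run_chain(self.data, self.spec, self.priors, config)
        return PKMixedResults(self, chain)


class PKMixedResults:
    """Posterior draws plus convenience summaries for a fitted model."""

    def __init__(self, model: PKMixedModel, chain):
        self.model = model
        self.chain = chain

    @property
    def config(self):
        return self.chain.config

    def _summary(self, window: Optional[int] = None):
        from .sampler import summarize_chain

        return summarize_chain(self.chain, window)

    @property
    def params(self):
        """Posterior means over the summary window (pandas Series)."""
        return self._summary().table["mean"]

    def conf_int(self, window: Optional[int] = None):
        """Equal-tailed 95% credible intervals (2.5/97.5 percentiles)."""
        return self._summary(window).table[["lower", "upper"]]

    def posterior_summary(self, window: Optional[int] = None):
        return self._summary(window)

    def derived_pk(self, offset: float = 0.0, window: Optional[int] = None):
        """Posterior summaries of tmax, cmax and half-life."""
        from .derived import posterior_derived

        return posterior_derived(self.chain, self.model.spec, offset=offset,
                                 window=window)

    def plugin_loglik(self, gh_nodes: int = 40) -> float:
        """Log likelihood at posterior means, random effects integrated out."""
        from .compare import marginal_plugin_loglik

        summ = self._summary()
        m = summ.table["mean"]
        return marginal_plugin_loglik(
            self.model.data, self.model.spec,
            beta=np.array([m["beta0"], m["beta1"], m["beta2"]]),
            sigma1=float(m["sigma1"]), sigma2=float(m["sigma2"]),
            gh_nodes=gh_nodes,
        )

    def aic(self, k: Optional[int] = None) -> float:
        """Plug-in AIC; by default k = 5 (three fixed effects + two
        variance components)."""
        from .compare import aic as _aic

        return _aic(self.plugin_loglik(), 5 if k is None else k)

    def ess(self):
        from .sampler import ess_and_trace

        return ess_and_trace(self.chain).ess

    def summary(self, window: Optional[int] = None) -> str:
        """Human-readable fit report (plain text)."""
        summ = self._summary(window)
        spec = self.model.spec
        lines = [
            "Robust Bayesian population PK fit",
            "=" * 46,
            f"error family : {spec.error_family}"
            + (f" (nu={spec.nu:g})" if spec.error_family == "t" else "")
            + (f" (shape={spec.gamma_shape:g})"
               if spec.error_family == "gamma" and spec.gamma_shape else ""),
            f"powers       : {spec.powers}",
            f"subjects     : {self.model.data.n_subjects}"
            f"   observations: {self.model.data.n_obs}",
            f"iterations   : {self.config.n_iter}"
            f"  burn-in: {self.config.burn_in}"
            f"  summary window: {summ.window}",
            "",
            summ.table.loc[
                [c for c in summ.table.index if not c.startswith("b_")]
            ].to_string(float_format=lambda v: f"{v: .6f}"),
            "",
            "acceptance rates: "
            + "  ".join(f"{k}={v:.2f}" for k, v in
                        self.chain.accept_rates.items()
                        if not np.isnan(v)),
        ]
        return "\n".join(lines)

    def save_chain(self, path) -> None:
        self.chain.to_frame().to_csv(path, index=False)

    def to_summary_dict(self, window: Optional[int] = None) -> dict:
        summ = self._summary(window)
        return {
            "family": self.model.spec.error_family,
            "powers": list(self.model.spec.powers),
            "nu": self.model.spec.nu
            if self.model.spec.error_family == "t" else None,
            "n_iter": self.config.n_iter,
            "burn_in": self.config.burn_in,
            "window": summ.window,
            "seed": self.config.seed,
            "accept_rates": {k: (None if np.isnan(v) else float(v))
                             for k, v in self.chain.accept_rates.items()},
            "estimates": {
                name: {
                    "mean": float(summ.table.loc[name, "mean"]),
                    "lower": float(summ.table.loc[name, "lower"]),
                    "upper": float(summ.table.loc[name, "upper"]),
                }
                for name in summ.table.index
            },
        }
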