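"""Derived pharmacokinetic parameters from the fitted population curve.

All quantities are computed from the fixed-effect (population) log
curve g(t) = beta0 + beta1*t**p1 + beta2*t**p2 with the random effect
at zero:

* ``tmax``  — argmax of g over t > 0; closed form sqrt(beta2/beta1)
  for the default powers (1, -1), golden-section search otherwise.
* ``cmax``  — exp(g(tmax) + offset); closed form
  exp(beta0 + offset - 2*sqrt(beta1*beta2)) for the default powers.
* half-life — reported in two explicit variants, because a single
  closed form does not exist for a fractional-polynomial curve:
  ``t_half_terminal`` = log(2)/(-beta1), the exponential-tail
  half-life (defined when p1 == 1), and ``t_half_descent``, the time
  past the peak at which the curve has fallen by a factor 2, found by
  bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .exceptions import NumericalError, PKDomainError
from .model import ModelSpec

__all__ = [
    "DerivedPKParams",
    "curve_tmax",
    "curve_cmax",
    "curve_thalf",
    "derived_from_beta",
    "posterior_derived",
    "DerivedSummary",
]

_DEFAULT_POWERS = (1.0, -1.0)


@dataclass(frozen=True)
class DerivedPKParams:
    tmax: float
    cmax: float
    t_half_terminal: float
    t_half_descent: float


def _log_curve(beta, powers):
    b0, b1, b2 = beta
    p1, p2 = powers

    def g(t):
        return b0 + b1 * t ** p1 + b2 * t ** p2

    return g


def curve_tmax(beta, spec: Optional[ModelSpec] = None,
               method: str = "auto") -> float:
    """Time of the population-curve maximum (hours).

    ``method="auto"`` uses the closed form sqrt(beta2/beta1) for the
    default powers and golden-section search otherwise;
    ``method="numeric"`` forces the search (useful as a cross-check).
    """
    spec = spec or ModelSpec()
    beta = np.asarray(beta, dtype=float)
    p = tuple(float(v) for v in spec.powers)
    if p == _DEFAULT_POWERS and method != "numeric":
        if not (beta[1] < 0 and beta[2] < 0):
            raise PKDomainError(
                "tmax requires beta1 < 0 and beta2 < 0 with powers (1, -1)"
            )
        return float(np.sqrt(beta[2] / beta[1]))
    g = _log_curve(beta, p)
    grid = np.logspace(-3, 3, 2001)
    vals = g(grid)
    i = int(np.argmax(vals))
    if i == 0 or i == grid.size - 1:
        raise PKDomainError(
            "curve has no interior maximum on (0.001, 1000) h; "
            "monotone for these coefficients"
        )
    res = minimize_scalar(lambda t: -g(t), method="golden",
                          bracket=(grid[i - 1], grid[i], grid[i + 1]),
                          options={"xtol": 1e-10})
    return float(res.x)


def curve_cmax(beta, spec: Optional[ModelSpec] = None,
               offset: float = 0.0) -> float:
    """Peak concentration exp(g(tmax) + offset)."""
    spec = spec or ModelSpec()
    beta = np.asarray(beta, dtype=float)
    p = tuple(float(v) for v in spec.powers)
    if p == _DEFAULT_POWERS:
        curve_tmax(beta, spec)  # validates existence
        return float(np.exp(beta[0] + offset
                            - 2.0 * np.sqrt(beta[1] * beta[2])))
    tm = curve_tmax(beta, spec)
    return float(np.exp(_log_curve(beta, p)(tm) + offset))


def curve_thalf(beta, spec: Optional[ModelSpec] = None):
    """Both half-life variants as ``(t_half_terminal, t_half_descent)``.

    The terminal value is log(2)/(-beta1) (NaN unless p1 == 1); the
    descent value solves g(t) = g(tmax) - log(2) for t > tmax by
    bisection to 1e-8.
    """
    spec = spec or ModelSpec()
    beta = np.asarray(beta, dtype=float)
    p = tuple(float(v) for v in spec.powers)
    terminal = float(np.log(2.0) / -beta[1]) if p[0] == 1.0 else float("nan")
    tm = curve_tmax(beta, spec)
    g = _log_curve(beta, p)
    target = g(tm) - np.log(2.0)
    hi = tm
    f_hi = g(hi) - target
    # bracket window: 1000*tmax, extended by the terminal time scale so a
    # very early peak (tmax -> 0) does not truncate the descent branch
    upper = max(1e3 * tm, tm + 1e3 * abs(terminal)
                if np.isfinite(terminal) else 1e3 * tm)
    while f_hi > 0 and hi < upper:
        hi *= 2.0
        f_hi = g(hi) - target
    if f_hi > 0:
        raise PKDomainError(
            "curve does not fall to half its peak within the search window"
        )
    descent = float(brentq(lambda t: g(t) - target, tm, hi, xtol=1e-10,
                           rtol=1e-12))
    return terminal, descent


def derived_from_beta(beta, spec: Optional[ModelSpec] = None,
                      offset: float = 0.0) -> DerivedPKParams:
    spec = spec or ModelSpec()
    tm = curve_tmax(beta, spec)
    cm = curve_cmax(beta, spec, offset)
    terminal, descent = curve_thalf(beta, spec)
    return DerivedPKParams(tmax=tm, cmax=cm, t_half_terminal=terminal,
                           t_half_descent=descent)


@dataclass(frozen=True)
class DerivedSummary:
    table: pd.DataFrame  # index: quantity; columns: mean, lower, upper
    n_draws: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "n_dropped": self.n_dropped,
            "quantities": {
                q: {k: float(self.table.loc[q, k])
                    for k in ("mean", "lower", "upper")}
                for q in self.table.index
            },
        }


def posterior_derived(chain, spec: Optional[ModelSpec] = None,
                      offset: float = 0.0,
                      window: Optional[int] = None) -> DerivedSummary:
    """Map each retained beta draw through the derived-parameter formulas.

    Draws for which a quantity is undefined (e.g. a monotone curve) are
    dropped and counted; more than 50% undefined draws is an error.
    """
    spec = spec or ModelSpec()
    retained = chain.retained
    if retained.shape[0] == 0:
        raise PKDomainError("chain has no retained draws")
    if window is None:
        window = min(chain.config.summary_window, retained.shape[0])
    tail = retained[-window:]
    cols = {name: chain.columns.index(name)
            for name in ("beta0", "beta1", "beta2")}
    rows = []
    dropped = 0
    for draw in tail:
        beta = np.array([draw[cols["beta0"]], draw[cols["beta1"]],
                         draw[cols["beta2"]]])
        try:
            d = derived_from_beta(beta, spec, offset)
        except PKDomainError:
            dropped += 1
            continue
        rows.append([d.tmax, d.cmax, d.t_half_terminal, d.t_half_descent])
    if dropped > 0.5 * tail.shape[0]:
        raise NumericalError(
            f"derived parameters undefined for {dropped}/{tail.shape[0]} draws"
        )
    arr = np.asarray(rows)
    lo, hi = np.nanpercentile(arr, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {"mean": np.nanmean(arr, axis=0), "lower": lo, "upper": hi},
        index=["tmax", "cmax", "t_half_terminal", "t_half_descent"],
    )
    return DerivedSummary(table=table, n_draws=len(rows), n_dropped=dropped)
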