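"""Synthetic concentration-time data with the simulation-study structure.

The canonical design: 10 subjects, a common 10 mg dose, 12 sampling
times [0.2, 0.5, 1, 2, 4, 8, 14, 22, 28, 30, 32, 36] h.  Log
concentrations are X beta_true + b_i + error with b_i ~ N(0, sigma1)
and errors either iid normal (variance sigma2) or multivariate t per
subject (scatter sigma2, df nu, simulated through the normal
scale-mixture representation).  Optionally a fixed shift is added to a
uniformly chosen fraction of log concentrations to emulate outlier
contamination.

Presets:

* Example 1 — beta (0.4, -0.04, -0.2), sigma1 = sigma2 = 0.008, normal
  errors, clean.
* Example 2 — beta (0.8, -0.04, -0.2), same variances, normal errors,
  5% shift outliers.
* Example 3 — beta (0.8, -0.04, -0.2), sigma1 = 0.01, sigma2 = 0.001,
  t errors (nu = 4), 5% shift outliers.

The generating values travel with the data in a "truth record" so
recovery tests never re-derive them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import build_design_matrix
from .data import ObservationBlock, PKDataset
from .exceptions import PKDomainError

__all__ = [
    "SimulationDesign",
    "simulate_dataset",
    "inject_outliers",
    "preset_example",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 14.0, 22.0, 28.0, 30.0,
                    32.0, 36.0)


@dataclass(frozen=True)
class SimulationDesign:
    """Complete generating configuration for one synthetic study."""

    n_subjects: int = 10
    dose: float = 10.0
    schedule: Tuple[float, ...] = DEFAULT_SCHEDULE
    beta_true: Tuple[float, float, float] = (0.4, -0.04, -0.2)
    sigma1_true: float = 0.008
    sigma2_true: float = 0.008
    error_family: str = "normal"
    nu: float = 4.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 1.0
    powers: Tuple[float, float] = (1.0, -1.0)
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.schedule, dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise PKDomainError(
                "schedule must be strictly positive and increasing"
            )
        if self.n_subjects < 1:
            raise PKDomainError("need at least one subject")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise PKDomainError("outlier_fraction must lie in [0, 0.5)")
        if self.error_family not in ("normal", "t"):
            raise PKDomainError("error_family must be 'normal' or 't'")
        if self.error_family == "t" and not self.nu > 2:
            raise PKDomainError("t errors require nu > 2")
        if self.sigma1_true < 0 or self.sigma2_true < 0:
            raise PKDomainError("generating variances must be non-negative")


def simulate_dataset(design: SimulationDesign
                     ) -> Tuple[PKDataset, Dict[str, object]]:
    """Draw one dataset; returns ``(dataset, truth_record)``.

    Deterministic given ``design.seed``.  The truth record carries the
    generating parameters, the drawn random intercepts and, when
    contamination is requested, the outlier mask (flat observation
    order).
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.schedule, dtype=float)
    X = build_design_matrix(t, design.powers)
    beta = np.asarray(design.beta_true, dtype=float)
    mean = X @ beta
    n = t.size
    m = design.n_subjects

    b = (np.sqrt(design.sigma1_true) * rng.standard_normal(m)
         if design.sigma1_true > 0 else np.zeros(m))
    blocks = []
    for i in range(m):
        if design.sigma2_true > 0:
            z = rng.standard_normal(n)
            if design.error_family == "t":
                w = rng.chisquare(design.nu) / design.nu
                eps = np.sqrt(design.sigma2_true) * z / np.sqrt(w)
            else:
                eps = np.sqrt(design.sigma2_true) * z
        else:
            eps = np.zeros(n)
        logc = mean + b[i] + eps
        blocks.append(
            ObservationBlock(subject_id=f"S{i + 1:02d}", times=t.copy(),
                             concentrations=np.exp(logc), dose=design.dose)
        )
    data = PKDataset(blocks)

    truth: Dict[str, object] = {
        "beta0": beta[0], "beta1": beta[1], "beta2": beta[2],
        "sigma1": design.sigma1_true, "sigma2": design.sigma2_true,
        "error_family": design.error_family,
        "nu": design.nu if design.error_family == "t" else None,
        "b": b.tolist(),
        "seed": design.seed,
        "outlier_fraction": design.outlier_fraction,
        "outlier_shift": design.outlier_shift,
        "outlier_mask": None,
    }
    if design.outlier_fraction > 0:
        out_seed = int(rng.integers(2 ** 31))
        data, mask = inject_outliers(data, design.outlier_fraction,
                                     design.outlier_shift, out_seed)
        truth["outlier_mask"] = mask.tolist()
    return data, truth


def inject_outliers(data: PKDataset, fraction: float, shift: float,
                    seed: Optional[int] = None
                    ) -> Tuple[PKDataset, np.ndarray]:
    """Add ``shift`` to the log concentration of a random 5%-style subset.

    Exactly ``round(fraction * n_obs)`` observations are picked
    uniformly without replacement (flat order across subjects); all
    other values are returned bit-identical.  Returns the contaminated
    dataset and the boolean mask in flat observation order.
    """
    if not (0.0 <= fraction < 0.5):
        raise PKDomainError("fraction must lie in [0, 0.5)")
    n_total = data.n_obs
    mask = np.zeros(n_total, dtype=bool)
    if fraction > 0:
        k = int(round(fraction * n_total))
        rng = np.random.default_rng(seed)
        mask[rng.choice(n_total, size=k, replace=False)] = True
    if not mask.any():
        return data, mask
    blocks = []
    pos = 0
    for blockdata in data:
        n = blockdata.n_obs
        sub = mask[pos:pos + n]
        pos += n
        if sub.any():
            conc = blockdata.concentrations.copy()
            conc[sub] = np.exp(np.log(conc[sub]) + shift)
            blocks.append(ObservationBlock(blockdata.subject_id,
                                           blockdata.times.copy(), conc,
                                           blockdata.dose))
        else:
            blocks.append(blockdata)
    return PKDataset(blocks), mask


def preset_example(k: int) -> SimulationDesign:
    """Return the generating design of simulation example 1, 2 or 3."""
    if k == 1:
        return SimulationDesign(beta_true=(0.4, -0.04, -0.2),
                                sigma1_true=0.008, sigma2_true=0.008,
                                error_family="normal", outlier_fraction=0.0)
    if k == 2:
        return SimulationDesign(beta_true=(0.8, -0.04, -0.2),
                                sigma1_true=0.008, sigma2_true=0.008,
                                error_family="normal",
                                outlier_fraction=0.05, outlier_shift=1.0)
    if k == 3:
        return SimulationDesign(beta_true=(0.8, -0.04, -0.2),
                                sigma1_true=0.01, sigma2_true=0.001,
                                error_family="t", nu=4.0,
                                outlier_fraction=0.05, outlier_shift=1.0)
    raise PKDomainError(f"unknown example {k!r}; choose 1, 2 or 3")


def write_truth(truth: Dict[str, object], path) -> None:
    """Write a truth record as a JSON sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=float)
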