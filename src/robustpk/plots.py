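"""Diagnostic figures: MCMC traces and predicted-vs-observed scatter.

Population predictions (``pred``) use the posterior-mean fixed effects
with the random effect at zero; individual predictions (``ipred``) add
each subject's posterior-mean intercept.  Filenames are deterministic
functions of the parameter names, so repeated runs overwrite in place.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import numpy as np

from .core import build_design_matrix, linear_predictor
from .data import PKDataset
from .exceptions import DataValidationError
from .model import ModelSpec
from .sampler import ChainResult, POPULATION_PARAMS, summarize_chain

__all__ = ["export_plots", "predictions"]


def predictions(chain: ChainResult, data: PKDataset, spec: ModelSpec,
                window: Optional[int] = None):
    """Flat arrays (dv, pred, ipred) across all observations."""
    summ = summarize_chain(chain, window)
    beta = np.array([summ.mean("beta0"), summ.mean("beta1"),
                     summ.mean("beta2")])
    dv, pred, ipred = [], [], []
    for i, block in enumerate(data):
        X = build_design_matrix(block.times, spec.powers)
        off = spec.offset_for(block.dose)
        eta = linear_predictor(X, beta, 0.0, off)
        b_i = summ.mean(f"b_{i + 1}") if f"b_{i + 1}" in summ.table.index else 0.0
        dv.append(block.concentrations)
        pred.append(np.exp(eta))
        ipred.append(np.exp(eta + b_i))
    return (np.concatenate(dv), np.concatenate(pred), np.concatenate(ipred))


def export_plots(chain: ChainResult, data: PKDataset, spec: ModelSpec,
                 outdir, window: Optional[int] = None) -> List[Path]:
    """Write trace plots per population parameter and pred/ipred scatter.

    Returns the list of written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataValidationError(f"cannot create output dir {outdir}: {exc}")
    written: List[Path] = []

    frame = chain.to_frame()
    for name in POPULATION_PARAMS:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(frame[name].to_numpy(), lw=0.5)
        if chain.burn_in:
            ax.axvline(chain.burn_in, color="red", ls="--", lw=0.8,
                       label="end of burn-in")
            ax.legend(loc="best", fontsize=8)
        ax.set_xlabel("iteration")
        ax.set_ylabel(name)
        ax.set_title(f"trace: {name}")
        path = outdir / f"trace_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    dv, pred, ipred = predictions(chain, data, spec, window)
    for label, vals in (("pred", pred), ("ipred", ipred)):
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        ax.scatter(vals, dv, s=14, alpha=0.7, edgecolor="none")
        lim = (0, 1.05 * max(float(dv.max()), float(vals.max())))
        ax.plot(lim, lim, color="grey", lw=0.8)
        ax.set_xlim(lim)
        ax.set_ylim(lim)
        ax.set_xlabel(f"{label} (model)")
        ax.set_ylabel("DV (observed)")
        ax.set_title(f"{label} vs observed")
        path = outdir / f"{label}_vs_dv.png"
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
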