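"""Allometric power-law fits of gene expression against the expression index.

Part-whole scaling theory predicts that the abundance of a single gene
(part) scales with the total expression of all genes (whole) as a power
law, y = alpha * EI**beta.  Fitting this per gene is a diagnostic check
that expression can be described as a smooth function of EI — the premise
of the quasi-dynamic ODE machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .expression import ExpressionIndex, ExpressionMatrix

__all__ = ["PowerFit", "fit_power_law", "screen_power_fit"]


@dataclass
class PowerFit:
    """A fitted power curve alpha * EI**beta for one gene."""

    alpha: float
    beta: float
    r2: float
    fitted: np.ndarray
    scale: str = "loglog"  # fitting scale the r2 refers to

    def predict(self, ei: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(ei, dtype=float) ** self.beta


def _prepare_y(y: np.ndarray) -> np.ndarray:
    """Shift zeros up by half the smallest positive value (log-scale fitting)."""
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("negative expression cannot be power-law fitted; shift first")
    if (y == 0).any():
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError("all-zero expression vector: degenerate power fit")
        y = y + 0.5 * pos.min() * (y == 0)
    return y


def fit_power_law(
    y: np.ndarray, e: ExpressionIndex, scale: str = "loglog"
) -> PowerFit:
    """Least-squares fit of y = alpha * EI**beta.

    ``scale="loglog"`` (default) fits ordinary least squares of log y on
    log EI, the standard approach in allometry; ``scale="raw"`` refines it
    by nonlinear least squares on the original scale.
    """
    ei = np.asarray(e.ei, dtype=float)
    if (ei <= 0).any():
        raise ValueError(
            "EI must be strictly positive for a power fit; apply an offset/shift"
        )
    y = _prepare_y(y)
    if len(y) != len(ei):
        raise ValueError("y and EI lengths differ")
    ly, le = np.log(y), np.log(ei)
    beta, loga = np.polyfit(le, ly, 1)
    alpha = float(np.exp(loga))
    if scale == "raw":
        (alpha, beta), _ = curve_fit(
            lambda x, a, b: a * x**b, ei, y, p0=(alpha, beta), maxfev=5000
        )
        resid = y - alpha * ei**beta
        tot = y - y.mean()
    elif scale == "loglog":
        resid = ly - (loga + beta * le)
        tot = ly - ly.mean()
    else:
        raise ValueError(f"unknown fitting scale {scale!r}")
    sst = float(tot @ tot)
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    fitted = alpha * ei**beta
    return PowerFit(alpha=float(alpha), beta=float(beta), r2=max(0.0, min(1.0, r2)),
                    fitted=fitted, scale=scale)


def screen_power_fit(
    x: ExpressionMatrix,
    e: ExpressionIndex,
    r2_min: float = 0.0,
    scale: str = "loglog",
) -> pd.DataFrame:
    """Per-gene power fits with a pass/fail flag at ``r2 >= r2_min``.

    Screening is diagnostic: the default threshold 0 flags nothing, and no
    gene is dropped by this stage.
    """
    rows = []
    for g, y in zip(x.gene_ids, x.values):
        fit = fit_power_law(y, e, scale=scale)
        rows.append(
            {"gene_id": g, "alpha": fit.alpha, "beta": fit.beta,
             "r2": fit.r2, "passed": fit.r2 >= r2_min}
        )
    return pd.DataFrame(rows).set_index("gene_id")
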