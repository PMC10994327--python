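"""Inequity-aversion reciprocity model and its per-participant grid fit.

The forward model maps a trial and a fairness norm ``delta`` in [0, 1] to
a predicted returned amount::

    R2 = max(0, (E - I + I*M) * delta - (E - I))

delta = 0 returns nothing, delta = 0.5 equalizes both players' payouts,
delta = 1 returns the whole pot.  The estimator minimizes SSE over an
even grid on [0, 1]; with the Gaussian maximum-likelihood plug-in scale
sigma^2 = SSE / n this is identical to minimizing deviance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ars import deviance_from_sse


def predict_return(E, I, M, delta):
    """Predicted returned amount; vectorized, bounded by [0, I*M]."""
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(I <= 0) or np.any(I > E):
        raise ValueError("need 0 < I <= E")
    if np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("delta must lie in [0, 1]")
    out = np.maximum(0.0, (E - I + I * M) * delta - (E - I))
    if out.ndim == 0:
        return float(out)
    return out


def variance_explained(predicted, observed) -> float:
    """1 - SSE / TSS about the observed mean; NaN when the observed
    sequence is constant (flagged as undefined)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D")
    if len(observed) < 2:
        raise ValueError("need at least 2 observations")
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0.0:
        return math.nan
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / tss


@dataclass(frozen=True)
class DeltaFit:
    participant_id: str
    delta_hat: float
    sse: float
    sigma_hat: float
    n: int
    r_squared: float  # NaN when the observed returns have zero variance
    deviance: float


def fit_delta(
    records: pd.DataFrame,
    grid_points: int = 101,
    on: str = "returned",
    participant_id: str = "",
) -> DeltaFit:
    """Grid-search fit of the fairness norm on one participant's
    unambiguous trials.

    ``records`` needs columns endowment, investment, multiplier, returned.
    ``on`` selects the residual scale: ``"returned"`` (currency, default)
    or ``"reciprocity"`` (returned / pot).  Ties go to the smallest delta.
    """
    if len(records) == 0:
        raise ValueError("no trials to fit")
    if on not in ("returned", "reciprocity"):
        raise ValueError(f"unknown residual scale {on!r}")
    E = records["endowment"].to_numpy(dtype=float)
    I = records["investment"].to_numpy(dtype=float)
    M = records["multiplier"].to_numpy(dtype=float)
    y = records["returned"].to_numpy(dtype=float)
    pot = I * M
    if on == "reciprocity":
        y = y / pot

    grid = np.linspace(0.0, 1.0, grid_points)
    pred = np.maximum(0.0, (E + (M - 1) * I)[None, :] * grid[:, None] - (E - I))
    if on == "reciprocity":
        pred = pred / pot[None, :]
    sse = ((pred - y[None, :]) ** 2).sum(axis=1)
    best = int(np.argmin(sse))  # first minimum = smallest delta
    n = len(y)
    sse_best = float(sse[best])
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = math.nan if tss == 0.0 else 1.0 - sse_best / tss
    return DeltaFit(
        participant_id=participant_id,
        delta_hat=float(grid[best]),
        sse=sse_best,
        sigma_hat=math.sqrt(sse_best / n),
        n=n,
        r_squared=r2,
        deviance=deviance_from_sse(sse_best, n),
    )


def fit_delta_cohort(
    choices: pd.DataFrame, grid_points: int = 101, on: str = "returned"
) -> pd.DataFrame:
    """Fit delta per participant on the unambiguous rows of a choice table."""
    unamb = choices[choices["condition"] == "unambiguous"]
    if len(unamb) == 0:
        raise ValueError("choice table has no unambiguous rows")
    fits = []
    for pid, group in unamb.groupby("participant_id", sort=True):
        f = fit_delta(group, grid_points=grid_points, on=on, participant_id=str(pid))
        fits.append(
            {
                "participant_id": f.participant_id,
                "delta_hat": f.delta_hat,
                "sse": f.sse,
                "sigma_hat": f.sigma_hat,
                "n": f.n,
                "r_squared": f.r_squared,
                "deviance": f.deviance,
            }
        )
    return pd.DataFrame(fits)
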