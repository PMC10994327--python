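"""Ambiguity-resolution-strategy (ARS) model: preference over candidate
endowments and per-participant grid-search fitting.

The two-parameter preference of a trustee for believing the hidden
endowment is ``E`` given an investment ``I``::

    p2(E) = (1 - |I/E - tau|) * (1 - psi) + (1 - |I/E - I/10|) * psi

``tau`` is the default assumed trustingness; ``psi`` weighs an
investment-magnitude heuristic.  Four single-strategy archetypes live at
fixed corners of the (tau, psi) square: HAT (1, 0), LAT (0, 0), MT
(0.5, 0) and HR (psi = 1).

Fitting objectives
------------------
``"choice"`` (default): the squared residual per trial is a 0/1 indicator
of disagreement between the model's preferred candidate and the candidate
the participant is inferred to have acted on.  SSE is then the count of
mispredicted trials.  This objective is piecewise constant in (tau, psi),
so parameter plateaus are resolved by a deterministic tie-break that
prefers archetype coordinates (see :func:`fit_ars_grid`).

``"preference_gap"``: the residual is ``max_E p2(E) - p2(E_observed)``,
i.e. the preference shortfall of the observed candidate.  Provided for
audit; it is degenerate as an estimator because it vanishes wherever the
model is indifferent between candidates, not only where it predicts the
observed choice (see package notes), and is therefore not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Archetype coordinates (tau, psi).  HR's tau is irrelevant (psi = 1);
#: it is pinned at 0.5 so the coordinate lies on every odd-sized grid.
ARCHETYPES: dict[str, tuple[float, float]] = {
    "MT": (0.5, 0.0),
    "LAT": (0.0, 0.0),
    "HAT": (1.0, 0.0),
    "HR": (0.5, 1.0),
}

SINGLE_STRATEGIES = ("HAT", "LAT", "MT", "HR")

_TOL = 1e-12


def preference(E, I, tau, psi):
    """Preference score p2 in [0, 1] for candidate endowment ``E``.

    Vectorized over any broadcastable combination of arguments.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("endowment must be positive")
    ratio = np.asarray(I, dtype=float) / E
    trust_match = 1.0 - np.abs(ratio - tau)
    heuristic_match = 1.0 - np.abs(ratio - np.asarray(I, dtype=float) / 10.0)
    out = trust_match * (1.0 - np.asarray(psi, dtype=float)) + heuristic_match * psi
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ARSFit:
    """Result of fitting one model to one participant's ambiguous trials."""

    participant_id: str
    model: str
    tau_hat: float
    psi_hat: float
    sse: float
    n: int
    k: int
    deviance: float
    objective: str = "choice"


def deviance_from_sse(sse: float, n: int) -> float:
    """Gaussian deviance with the MLE plug-in scale sigma^2 = SSE / n.

    Monotone in SSE at fixed n; -inf for a perfect fit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        return -math.inf
    return n * math.log(2.0 * math.pi * sse / n) + n


def _trial_arrays(table: pd.DataFrame):
    """Unpack an ambiguous-trial table into candidate/observation arrays.

    ``table`` needs columns investment, cand1..cand3 (ascending) and
    observed_candidate.  Rows with missing observed_candidate are dropped.
    """
    table = table.dropna(subset=["observed_candidate"])
    if len(table) == 0:
        raise ValueError("no usable ambiguous trials")
    cands = table[["cand1", "cand2", "cand3"]].to_numpy(dtype=float)
    if np.any(np.diff(cands, axis=1) <= 0):
        raise ValueError("candidate endowments must be ascending per trial")
    inv = table["investment"].to_numpy(dtype=float)
    obs = table["observed_candidate"].to_numpy(dtype=float)
    obs_idx = np.argmin(np.abs(cands - obs[:, None]), axis=1)
    ratio = inv[:, None] / cands
    heur = 1.0 - np.abs(ratio - inv[:, None] / 10.0)
    return cands, ratio, heur, obs_idx


def _predicted_index(p2: np.ndarray) -> np.ndarray:
    """Argmax over the candidate axis, ties broken toward the smallest
    endowment (candidates are ascending, first max wins)."""
    mx = p2.max(axis=-1, keepdims=True)
    return np.asarray(p2 >= mx - _TOL).argmax(axis=-1)


def _objective_sse(p2: np.ndarray, obs_idx: np.ndarray, objective: str) -> np.ndarray:
    """SSE over trials for a stack of parameter points.

    ``p2`` has shape (..., T, 3); returns shape (...,).
    """
    pred_idx = _predicted_index(p2)
    if objective == "choice":
        return (pred_idx != obs_idx).sum(axis=-1).astype(float)
    if objective == "preference_gap":
        mx = p2.max(axis=-1)
        obs_pref = np.take_along_axis(
            p2, np.broadcast_to(obs_idx, pred_idx.shape)[..., None], axis=-1
        )[..., 0]
        return ((mx - obs_pref) ** 2).sum(axis=-1)
    raise ValueError(f"unknown objective {objective!r}")


def evaluate_point(
    table: pd.DataFrame, tau: float, psi: float, objective: str = "choice"
) -> float:
    """SSE of the ARS objective at a single (tau, psi) point."""
    _, ratio, heur, obs_idx = _trial_arrays(table)
    p2 = (1.0 - np.abs(ratio - tau)) * (1.0 - psi) + heur * psi
    return float(_objective_sse(p2, obs_idx, objective))


def preference_pairs(table: pd.DataFrame, tau: float, psi: float) -> pd.DataFrame:
    """Per-trial (predicted, observed) preference scores at one grid point.

    predicted is p2 at the model's preferred candidate, observed is p2 at
    the candidate the participant acted on; predicted >= observed always.
    """
    _, ratio, heur, obs_idx = _trial_arrays(table)
    p2 = (1.0 - np.abs(ratio - tau)) * (1.0 - psi) + heur * psi
    predicted = p2.max(axis=-1)
    observed = p2[np.arange(len(p2)), obs_idx]
    return pd.DataFrame(
        {
            "trial_index": table.dropna(subset=["observed_candidate"])[
                "trial_index"
            ].to_numpy(),
            "predicted": predicted,
            "observed": observed,
        }
    )


def sse_surface(
    table: pd.DataFrame, grid_points: int = 101, objective: str = "choice"
) -> np.ndarray:
    """SSE at every (tau, psi) coordinate pair of the fitting grid.

    Returns a (grid_points, grid_points) array indexed [tau, psi]; the
    default grid evaluates 101 x 101 = 10201 parameter combinations.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    _, ratio, heur, obs_idx = _trial_arrays(table)
    grid = np.linspace(0.0, 1.0, grid_points)
    trust = 1.0 - np.abs(ratio[None, :, :] - grid[:, None, None])  # (G,T,3)
    sse = np.empty((grid_points, grid_points))
    for j, psi in enumerate(grid):
        p2 = trust * (1.0 - psi) + heur[None, :, :] * psi
        sse[:, j] = _objective_sse(p2, obs_idx[None, :], objective)
    return sse


def fit_ars_grid(
    table: pd.DataFrame,
    grid_points: int = 101,
    objective: str = "choice",
    participant_id: str = "",
) -> ARSFit:
    """Exhaustive NLL grid search over the (tau, psi) square.

    Evaluates all ``grid_points**2`` coordinate pairs (10201 by default)
    and returns the deviance-minimizing point.  Among exactly tied minima
    the archetype coordinates (MT, LAT, HAT, HR in that order) are
    preferred; otherwise the smallest psi, then the smallest tau, wins.
    The archetype preference makes noiseless single-strategy agents
    recover their generating coordinates exactly, which bare
    lexicographic tie-breaking cannot do (the zero-SSE set of a
    choice-pattern objective is a plateau, not a point).
    """
    _, _, _, obs_idx = _trial_arrays(table)
    n = len(obs_idx)
    grid = np.linspace(0.0, 1.0, grid_points)
    sse = sse_surface(table, grid_points, objective)
    best = sse.min()
    tied = np.argwhere(sse <= best + _TOL)
    tied_set = {(int(i), int(j)) for i, j in tied}

    choice = None
    for name in ("MT", "LAT", "HAT", "HR"):
        tau_a, psi_a = ARCHETYPES[name]
        ij = (_grid_index(grid, tau_a), _grid_index(grid, psi_a))
        if None not in ij and (ij[0], ij[1]) in tied_set:
            choice = ij
            break
    if choice is None:
        # smallest psi, then smallest tau
        choice = min(tied_set, key=lambda ij: (ij[1], ij[0]))

    i, j = choice
    return ARSFit(
        participant_id=participant_id,
        model="ARS",
        tau_hat=float(grid[i]),
        psi_hat=float(grid[j]),
        sse=float(sse[i, j]),
        n=n,
        k=2,
        deviance=deviance_from_sse(float(sse[i, j]), n),
        objective=objective,
    )


def _grid_index(grid: np.ndarray, value: float) -> int | None:
    hits = np.nonzero(np.abs(grid - value) < 1e-9)[0]
    return int(hits[0]) if len(hits) else None


def fit_single_strategy(
    table: pd.DataFrame,
    strategy: str,
    objective: str = "choice",
    participant_id: str = "",
) -> ARSFit:
    """Evaluate the objective at a fixed archetype point (k = 0)."""
    if strategy not in ARCHETYPES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {SINGLE_STRATEGIES}"
        )
    tau, psi = ARCHETYPES[strategy]
    sse = evaluate_point(table, tau, psi, objective)
    n = len(table.dropna(subset=["observed_candidate"]))
    return ARSFit(
        participant_id=participant_id,
        model=strategy,
        tau_hat=tau,
        psi_hat=psi,
        sse=sse,
        n=n,
        k=0,
        deviance=deviance_from_sse(sse, n),
        objective=objective,
    )


def fit_participant_models(
    table: pd.DataFrame,
    grid_points: int = 101,
    objective: str = "choice",
    participant_id: str = "",
) -> list[ARSFit]:
    """ARS grid fit plus the four single-strategy fits for one participant."""
    fits = [
        fit_ars_grid(table, grid_points, objective, participant_id=participant_id)
    ]
    for strategy in SINGLE_STRATEGIES:
        fits.append(
            fit_single_strategy(table, strategy, objective, participant_id)
        )
    return fits


def fits_to_frame(fits: list[ARSFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": f.participant_id,
                "model": f.model,
                "tau_hat": f.tau_hat,
                "psi_hat": f.psi_hat,
                "sse": f.sse,
                "n": f.n,
                "k": f.k,
                "deviance": f.deviance,
                "objective": f.objective,
            }
            for f in fits
        ]
    )
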