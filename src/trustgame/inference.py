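"""Reverse inference of the hidden endowment from an observed return.

At multiplier 4 the forward model is linear in E wherever its max() does
not bind, so it inverts exactly::

    R2 = (E + 3I) * delta - (E - I)   =>   E = (R2 - I - 3*I*delta) / (delta - 1)

The published rearrangement omits the ``- I`` term in the numerator; it
is kept behind the ``printed_eq2`` method switch for audit and differs
from the exact inverse by exactly I / (delta - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import AMBIGUOUS, SessionDesign
from .reciprocity import predict_return

EXACT_INVERSE = "exact_inverse"
PRINTED_EQ2 = "printed_eq2"


class SingularInversionError(ValueError):
    """delta = 1 returns the whole pot for every endowment; no inverse."""


@dataclass(frozen=True)
class EndowmentInference:
    e_inferred: float
    snapped_candidate: float
    method: str
    censored: bool
    participant_id: str = ""
    trial_index: int = -1


def invert_exact_unclamped(R2: float, I: float, delta: float) -> float:
    """Algebraic inverse of the forward model at M = 4, before clamping."""
    if delta == 1.0:
        raise SingularInversionError("delta = 1 is singular")
    return (R2 - I - 3.0 * I * delta) / (delta - 1.0)


def snap_candidate(value: float, candidates: Sequence[float]) -> float:
    """Nearest candidate endowment; ties break toward the smaller one."""
    cands = np.asarray(sorted(candidates), dtype=float)
    return float(cands[int(np.argmin(np.abs(cands - value)))])


def invert_return_exact(
    R2: float, I: float, delta: float, candidates: Sequence[float]
) -> EndowmentInference:
    """Infer the endowment from a return via the exact inverse.

    The result is clamped to the candidate range.  A zero return censors
    the inversion (the forward model's max() may bind); such trials are
    flagged and assigned the largest candidate consistent with a zero
    prediction, which is always the largest candidate since the
    prediction decreases in E.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if delta == 1.0:
        raise SingularInversionError("delta = 1 is singular")
    cands = sorted(float(c) for c in candidates)
    if R2 <= 0.0:
        e = cands[-1]
        return EndowmentInference(
            e_inferred=e,
            snapped_candidate=e,
            method=EXACT_INVERSE,
            censored=True,
        )
    raw = invert_exact_unclamped(R2, I, delta)
    e = min(max(raw, cands[0]), cands[-1])
    return EndowmentInference(
        e_inferred=e,
        snapped_candidate=snap_candidate(e, cands),
        method=EXACT_INVERSE,
        censored=False,
    )


def invert_return_printed(R2: float, I: float, delta: float, E_max: float) -> float:
    """Literal evaluation of the published rearrangement, for audit:
    min((R2 - 3*I*delta) / (delta - 1), E_max)."""
    if delta == 1.0:
        raise SingularInversionError("delta = 1 is singular")
    return min((R2 - 3.0 * I * delta) / (delta - 1.0), E_max)


def infer_endowments(
    choices: pd.DataFrame,
    delta_fits: pd.DataFrame,
    design: SessionDesign,
    method: str = EXACT_INVERSE,
) -> pd.DataFrame:
    """Per-trial endowment inference for every participant's ambiguous rows.

    ``choices`` is a simulator-schema choice table; ``delta_fits`` maps
    participant_id to delta_hat.  Participants whose fitted delta is 1
    (singular) get NaN inferences, flagged in the ``singular`` column.
    """
    if method not in (EXACT_INVERSE, PRINTED_EQ2):
        raise ValueError(f"unknown inversion method {method!r}")
    deltas = delta_fits.set_index("participant_id")["delta_hat"]
    trial_map = {t.trial_index: t for t in design.trials}
    rows = []
    amb = choices[choices["condition"] == AMBIGUOUS]
    for rec in amb.itertuples(index=False):
        trial = trial_map[int(rec.trial_index)]
        delta = float(deltas.loc[rec.participant_id])
        cands = [float(c) for c in trial.candidate_endowments]
        if delta == 1.0:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial_index": rec.trial_index,
                    "e_inferred": math.nan,
                    "snapped_candidate": math.nan,
                    "method": method,
                    "censored": False,
                    "singular": True,
                }
            )
            continue
        if method == EXACT_INVERSE:
            inf = invert_return_exact(float(rec.returned), trial.investment, delta, cands)
            e, snapped, censored = inf.e_inferred, inf.snapped_candidate, inf.censored
        else:
            censored = float(rec.returned) <= 0.0
            if censored:
                e = cands[-1]
            else:
                e = invert_return_printed(
                    float(rec.returned), trial.investment, delta, cands[-1]
                )
                e = min(max(e, cands[0]), cands[-1])
            snapped = snap_candidate(e, cands)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "trial_index": rec.trial_index,
                "e_inferred": e,
                "snapped_candidate": snapped,
                "method": method,
                "censored": censored,
                "singular": False,
            }
        )
    return pd.DataFrame(rows)


def ambiguous_table(design: SessionDesign, inferences: pd.DataFrame) -> pd.DataFrame:
    """Join inferences with trial structure into the ARS fitting schema:
    one row per (participant, ambiguous trial) with investment, cand1..3
    and observed_candidate (NaN where inference was singular)."""
    trial_rows = []
    for t in design.ambiguous:
        trial_rows.append(
            {
                "trial_index": t.trial_index,
                "investment": t.investment,
                "cand1": t.candidate_endowments[0],
                "cand2": t.candidate_endowments[1],
                "cand3": t.candidate_endowments[2],
            }
        )
    trials = pd.DataFrame(trial_rows)
    merged = inferences.merge(trials, on="trial_index", how="left")
    merged = merged.rename(columns={"snapped_candidate": "observed_candidate"})
    return merged[
        [
            "participant_id",
            "trial_index",
            "investment",
            "cand1",
            "cand2",
            "cand3",
            "observed_candidate",
            "censored",
        ]
    ]
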