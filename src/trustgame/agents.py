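"""Synthetic trustees: generate choice data with known parameters.

An agent carries a fairness norm (delta), an ambiguity-resolution
preference (tau, psi) and a response-noise scale.  On ambiguous trials it
first resolves the hidden endowment to the preference-maximizing
candidate, then returns the forward-model amount plus truncated-Gaussian
noise scaled by the pot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ars import ARCHETYPES, preference
from .design import AMBIGUOUS, SessionDesign, TrialSpec
from .reciprocity import predict_return


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic trustee."""

    delta: float
    tau: float
    psi: float
    noise_sd: float = 0.0  # proportion of the pot
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("delta", "tau", "psi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def archetype_agent(strategy: str, delta: float, noise_sd: float = 0.0) -> AgentParams:
    """Agent at a single-strategy archetype coordinate."""
    tau, psi = ARCHETYPES[strategy]
    return AgentParams(delta=delta, tau=tau, psi=psi, noise_sd=noise_sd, label=strategy)


@dataclass(frozen=True)
class ChoiceRecord:
    participant_id: str
    trial_index: int
    returned: float
    pot: float
    reciprocity: float
    resolved_endowment: float | None = None  # only known for simulated agents

    def __post_init__(self) -> None:
        if not (0.0 <= self.returned <= self.pot + 1e-9):
            raise ValueError("returned must lie in [0, pot]")


def resolve_endowment(agent: AgentParams, trial: TrialSpec) -> int:
    """Candidate endowment maximizing the agent's preference; ties break
    toward the smaller endowment.  Usage error on unambiguous trials."""
    if trial.condition != AMBIGUOUS:
        raise ValueError("resolve_endowment applies to ambiguous trials only")
    cands = np.asarray(trial.candidate_endowments, dtype=float)
    scores = preference(cands, trial.investment, agent.tau, agent.psi)
    best = scores.max()
    idx = int(np.argmax(scores >= best - 1e-12))  # candidates ascending
    return int(trial.candidate_endowments[idx])


def simulate_return(
    agent: AgentParams, trial: TrialSpec, rng: np.random.Generator
) -> ChoiceRecord:
    """One trial's return: forward model at the acted-on endowment plus
    Gaussian noise of scale noise_sd * pot truncated to [0, pot]."""
    if trial.condition == AMBIGUOUS:
        acted = resolve_endowment(agent, trial)
    else:
        acted = trial.endowment
    pot = float(trial.pot)
    pred = predict_return(acted, trial.investment, trial.multiplier, agent.delta)
    if agent.noise_sd == 0.0:
        returned = pred
    else:
        scale = agent.noise_sd * pot
        a = (0.0 - pred) / scale
        b = (pot - pred) / scale
        returned = float(
            stats.truncnorm.rvs(a, b, loc=pred, scale=scale, random_state=rng)
        )
    return ChoiceRecord(
        participant_id="",
        trial_index=trial.trial_index,
        returned=returned,
        pot=pot,
        reciprocity=returned / pot,
        resolved_endowment=float(acted) if trial.condition == AMBIGUOUS else None,
    )


def simulate_session(
    agent: AgentParams,
    design: SessionDesign,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> pd.DataFrame:
    rows = []
    for trial in design.trials:
        rec = simulate_return(agent, trial, rng)
        rows.append(
            {
                "participant_id": participant_id,
                "trial_index": trial.trial_index,
                "condition": trial.condition,
                "endowment": trial.endowment,
                "investment": trial.investment,
                "multiplier": trial.multiplier,
                "pot": rec.pot,
                "returned": rec.returned,
                "reciprocity": rec.reciprocity,
                "resolved_endowment": rec.resolved_endowment,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    mixture: Sequence[tuple[AgentParams, int]],
    design: SessionDesign,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort from a list of (agent, count) groups.

    Each participant gets an independent substream of ``seed`` keyed by
    their position, so growing the cohort does not reshuffle earlier
    participants' data.  Returns (choices, ground_truth).
    """
    if len(mixture) == 0 or all(count < 1 for _, count in mixture):
        raise ValueError("mixture must contain at least one agent")
    choice_frames = []
    truth_rows = []
    pid_counter = 0
    for agent, count in mixture:
        if count < 1:
            raise ValueError("mixture counts must be >= 1")
        for _ in range(count):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            rng = np.random.default_rng([seed, 7, pid_counter])
            choice_frames.append(simulate_session(agent, design, rng, pid))
            truth_rows.append(
                {
                    "participant_id": pid,
                    "delta": agent.delta,
                    "tau": agent.tau,
                    "psi": agent.psi,
                    "noise_sd": agent.noise_sd,
                    "strategy_label": agent.label,
                }
            )
    return pd.concat(choice_frames, ignore_index=True), pd.DataFrame(truth_rows)


def bonus_payment(record: ChoiceRecord, trial: TrialSpec) -> float:
    """Bonus in EUR for one trial: (trustee payout / total money) * 16."""
    payout = record.pot - record.returned
    total = (trial.endowment - trial.investment) + record.pot
    return payout / total * 16.0
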