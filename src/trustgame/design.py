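"""Session design for the two-condition Trust Game task.

A session is 40 unambiguous trials (endowment visible) followed by 80
ambiguous trials (endowment hidden behind three candidate values).  The
ambiguous block composition is fixed; the unambiguous block is driven by a
frequency-table config whose shipped default has modal endowment 10 and
modal transfer of half the endowment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"

#: Closed [lo, hi] bestowed-trust (I/E) intervals.
TRUST_BANDS = {
    "low": (0.05, 0.25),
    "medium": (0.35, 0.50),
    "high": (0.70, 1.00),
}

_BAND_TOL = 1e-9

#: Ambiguous block composition: (n_trials, allowed investments, candidates).
AMBIGUOUS_BLOCKS = (
    (20, (2,), (2, 5, 10)),
    (20, (4, 5), (5, 10, 20)),
    (40, (7, 8, 9, 10), (10, 20, 50)),
)

MULTIPLIER = 4


class DesignError(ValueError):
    """Raised when a design config is internally inconsistent."""


def trust_band(ratio: float) -> str:
    """Band membership of a bestowed-trust ratio I/E.

    Returns ``"low"``, ``"medium"`` or ``"high"`` by closed-interval test,
    or ``"unbanded"`` for ratios falling in the gaps between intervals.

    Raises
    ------
    ValueError
        If ``ratio`` is outside (0, 1].
    """
    if not (0.0 < ratio <= 1.0 + _BAND_TOL):
        raise ValueError(f"trust ratio must be in (0, 1], got {ratio!r}")
    for name, (lo, hi) in TRUST_BANDS.items():
        if lo - _BAND_TOL <= ratio <= hi + _BAND_TOL:
            return name
    return "unbanded"


@dataclass(frozen=True)
class TrialSpec:
    """One round of the game as presented to the trustee."""

    trial_index: int
    condition: str
    endowment: int
    investment: int
    trust_band: str
    multiplier: int = MULTIPLIER
    candidate_endowments: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.investment <= self.endowment):
            raise ValueError(
                f"need 0 < I <= E, got I={self.investment}, E={self.endowment}"
            )
        if self.condition == AMBIGUOUS:
            cands = self.candidate_endowments
            if cands is None or len(cands) != 3:
                raise ValueError("ambiguous trials need exactly 3 candidate endowments")
            if tuple(sorted(cands)) != tuple(cands):
                raise ValueError("candidate endowments must be sorted ascending")
            if any(c < self.investment for c in cands):
                raise ValueError("every candidate endowment must be >= investment")
            if self.endowment not in cands:
                raise ValueError("true endowment must be among the candidates")
        elif self.condition == UNAMBIGUOUS:
            if self.candidate_endowments is not None:
                raise ValueError("unambiguous trials carry no candidate endowments")
        else:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def pot(self) -> int:
        """Amount the trustee controls: I x M."""
        return self.investment * self.multiplier

    @property
    def e_max(self) -> int:
        if self.candidate_endowments is None:
            return self.endowment
        return self.candidate_endowments[-1]


#: Default unambiguous frequency table: (endowment, investment, n_trials).
#: Emulates the published design constraints: modal endowment 10, modal
#: transfer E/2, low/medium/high bestowed trust all represented.
DEFAULT_UNAMBIGUOUS_ROWS: tuple[tuple[int, int, int], ...] = (
    (10, 5, 12),
    (10, 2, 4),
    (10, 8, 4),
    (10, 4, 2),
    (10, 10, 2),
    (5, 1, 2),
    (5, 2, 2),
    (5, 5, 2),
    (20, 2, 2),
    (20, 10, 3),
    (20, 16, 2),
    (50, 10, 1),
    (50, 25, 1),
    (50, 40, 1),
)


@dataclass(frozen=True)
class DesignConfig:
    """Frequency table driving the unambiguous block."""

    unambiguous_rows: tuple[tuple[int, int, int], ...] = DEFAULT_UNAMBIGUOUS_ROWS
    n_unambiguous: int = 40

    def digest(self) -> str:
        payload = json.dumps(
            {"rows": self.unambiguous_rows, "n": self.n_unambiguous}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SessionDesign:
    """An ordered 120-trial session: 40 unambiguous then 80 ambiguous."""

    trials: tuple[TrialSpec, ...]
    seed: int
    config_digest: str

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def unambiguous(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.condition == UNAMBIGUOUS)

    @property
    def ambiguous(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.condition == AMBIGUOUS)

    def by_index(self, trial_index: int) -> TrialSpec:
        return self._index_map()[trial_index]

    def _index_map(self) -> dict[int, TrialSpec]:
        return {t.trial_index: t for t in self.trials}


def generate_unambiguous_trials(
    n_trials: int, config: DesignConfig | None = None, seed: int = 0
) -> list[TrialSpec]:
    """Expand the config frequency table into ``n_trials`` shuffled trials.

    Raises :class:`DesignError` when the table's counts do not sum to
    ``n_trials``.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise DesignError("n_trials must be >= 1")
    config = config or DesignConfig()
    total = sum(c for _, _, c in config.unambiguous_rows)
    if total != n_trials:
        raise DesignError(
            f"config frequencies sum to {total}, expected n_trials={n_trials}"
        )
    trials: list[TrialSpec] = []
    for endowment, investment, count in config.unambiguous_rows:
        band = trust_band(investment / endowment)
        for _ in range(count):
            trials.append(
                TrialSpec(
                    trial_index=0,
                    condition=UNAMBIGUOUS,
                    endowment=endowment,
                    investment=investment,
                    trust_band=band,
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [
        replace(trials[j], trial_index=i + 1) for i, j in enumerate(order)
    ]


def generate_ambiguous_trials(seed: int = 0) -> list[TrialSpec]:
    """Generate the fixed 20/20/40 ambiguous block composition.

    Within a block the investment is drawn uniformly from the printed range
    and the true endowment uniformly from the candidate set; block membership
    is then shuffled across the 80 trial slots.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for count, investments, candidates in AMBIGUOUS_BLOCKS:
        for _ in range(count):
            inv = int(rng.choice(investments))
            endow = int(rng.choice(candidates))
            trials.append(
                TrialSpec(
                    trial_index=0,
                    condition=AMBIGUOUS,
                    endowment=endow,
                    investment=inv,
                    trust_band=trust_band(inv / endow),
                    candidate_endowments=tuple(candidates),
                )
            )
    order = rng.permutation(len(trials))
    return [replace(trials[j], trial_index=i + 1) for i, j in enumerate(order)]


def build_session(config: DesignConfig | None = None, seed: int = 0) -> SessionDesign:
    """Assemble a full session: unambiguous block first, then ambiguous.

    Uses per-stage substreams of ``seed`` so the two blocks are independent.
    """
    config = config or DesignConfig()
    unamb = generate_unambiguous_trials(
        config.n_unambiguous, config, seed=np.random.SeedSequence([seed, 1]).entropy
    )
    amb = generate_ambiguous_trials(seed=np.random.SeedSequence([seed, 2]).entropy)
    trials = list(unamb) + [
        replace(t, trial_index=t.trial_index + len(unamb)) for t in amb
    ]
    return SessionDesign(
        trials=tuple(trials), seed=seed, config_digest=config.digest()
    )


def session_to_frame(session: SessionDesign) -> pd.DataFrame:
    """One row per trial: trial_index, condition, endowment, investment,
    multiplier, cand1..cand3 (empty for unambiguous rows), trust_band."""
    rows = []
    for t in session.trials:
        cands = t.candidate_endowments or (None, None, None)
        rows.append(
            {
                "trial_index": t.trial_index,
                "condition": t.condition,
                "endowment": t.endowment,
                "investment": t.investment,
                "multiplier": t.multiplier,
                "cand1": cands[0],
                "cand2": cands[1],
                "cand3": cands[2],
                "trust_band": t.trust_band,
            }
        )
    return pd.DataFrame(rows)


def frame_to_session(
    frame: pd.DataFrame, seed: int = -1, config_digest: str = ""
) -> SessionDesign:
    """Inverse of :func:`session_to_frame` (seed/digest not recoverable)."""
    trials = []
    for row in frame.itertuples(index=False):
        cands = None
        if row.condition == AMBIGUOUS:
            cands = tuple(int(c) for c in (row.cand1, row.cand2, row.cand3))
        trials.append(
            TrialSpec(
                trial_index=int(row.trial_index),
                condition=row.condition,
                endowment=int(row.endowment),
                investment=int(row.investment),
                trust_band=row.trust_band,
                multiplier=int(row.multiplier),
                candidate_endowments=cands,
            )
        )
    return SessionDesign(tuple(trials), seed=seed, config_digest=config_digest)
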