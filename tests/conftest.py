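import numpy as np
import pandas as pd
import pytest

from trustgame.agents import AgentParams, simulate_session
from trustgame.design import DesignConfig, build_session
from trustgame.inference import ambiguous_table, infer_endowments
from trustgame.reciprocity import fit_delta_cohort


@pytest.fixture(scope="session")
def session_design():
    return build_session(DesignConfig(), seed=0)


@pytest.fixture(scope="session")
def another_session():
    return build_session(DesignConfig(), seed=99)


def simulate_and_invert(agent: AgentParams, design, seed: int = 0) -> pd.DataFrame:
    """Run one agent through the full simulate -> fit delta -> invert chain
    and return the ARS fitting table (with observed_candidate)."""
    rng = np.random.default_rng([seed, 11])
    choices = simulate_session(agent, design, rng, participant_id="P001")
    delta_fits = fit_delta_cohort(choices)
    inferences = infer_endowments(choices, delta_fits, design)
    return ambiguous_table(design, inferences)


@pytest.fixture(scope="session")
def mt_noiseless_table(session_design):
    return simulate_and_invert(
        AgentParams(delta=0.5, tau=0.5, psi=0.0, label="MT"), session_design
    )
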