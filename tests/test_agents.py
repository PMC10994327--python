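import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trustgame.agents import (
    AgentParams,
    ChoiceRecord,
    archetype_agent,
    bonus_payment,
    resolve_endowment,
    simulate_cohort,
    simulate_return,
    simulate_session,
)
from trustgame.design import TrialSpec


def amb_trial(investment, candidates, endowment=None, index=41):
    endowment = endowment if endowment is not None else candidates[0]
    from trustgame.design import trust_band

    return TrialSpec(
        index,
        "ambiguous",
        endowment,
        investment,
        trust_band(investment / endowment),
        4,
        tuple(candidates),
    )


class TestAgentParams:
    @pytest.mark.parametrize("field", ["delta", "tau", "psi"])
    @pytest.mark.parametrize("value", [-0.1, 1.1])
    def test_unit_interval_enforced(self, field, value):
        kwargs = {"delta": 0.5, "tau": 0.5, "psi": 0.5, field: value}
        with pytest.raises(ValueError):
            AgentParams(**kwargs)

    def test_negative_noise(self):
        with pytest.raises(ValueError):
            AgentParams(0.5, 0.5, 0.5, noise_sd=-1)

    def test_archetypes(self):
        assert archetype_agent("HAT", 0.5).tau == 1.0
        assert archetype_agent("LAT", 0.5).tau == 0.0
        assert archetype_agent("MT", 0.5).tau == 0.5
        assert archetype_agent("HR", 0.5).psi == 1.0


class TestResolveEndowment:
    def test_modal_trust_picks_middle(self):
        # p2 at tau=0.5, psi=0: E=2 -> 0.5, E=5 -> 0.9, E=10 -> 0.7
        agent = AgentParams(0.5, 0.5, 0.0)
        assert resolve_endowment(agent, amb_trial(2, (2, 5, 10))) == 5

    def test_heuristic_picks_ten(self):
        # psi=1: second term is maximal where I/E = I/10, i.e. E = 10
        agent = AgentParams(0.5, 0.0, 1.0)
        assert resolve_endowment(agent, amb_trial(2, (2, 5, 10))) == 10

    @pytest.mark.parametrize(
        "investment,candidates",
        [(2, (2, 5, 10)), (4, (5, 10, 20)), (5, (5, 10, 20)), (7, (10, 20, 50))],
    )
    def test_highest_assumed_trust_picks_smallest(self, investment, candidates):
        agent = AgentParams(0.5, 1.0, 0.0)
        assert resolve_endowment(agent, amb_trial(investment, candidates)) == min(
            candidates
        )

    def test_unambiguous_trial_rejected(self):
        agent = AgentParams(0.5, 0.5, 0.0)
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        with pytest.raises(ValueError):
            resolve_endowment(agent, trial)


class TestSimulateReturn:
    def test_equal_split_at_half(self):
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        rec = simulate_return(AgentParams(0.5, 0.5, 0.0), trial, np.random.default_rng(0))
        assert rec.returned == pytest.approx(7.5)
        investor_payout = trial.endowment - trial.investment + rec.returned
        trustee_payout = trial.pot - rec.returned
        assert investor_payout == pytest.approx(trustee_payout) == pytest.approx(12.5)

    def test_delta_zero_returns_nothing(self):
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        rec = simulate_return(AgentParams(0.0, 0.5, 0.0), trial, np.random.default_rng(0))
        assert rec.returned == 0.0

    def test_delta_one_returns_pot(self):
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        rec = simulate_return(AgentParams(1.0, 0.5, 0.0), trial, np.random.default_rng(0))
        assert rec.returned == pytest.approx(trial.pot)

    @given(
        delta=st.floats(min_value=0, max_value=1),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_noisy_returns_respect_game_rules(self, delta, seed):
        trial = amb_trial(7, (10, 20, 50))
        agent = AgentParams(delta, 0.5, 0.0, noise_sd=0.2)
        rec = simulate_return(agent, trial, np.random.default_rng(seed))
        assert 0.0 <= rec.returned <= trial.pot
        assert 0.0 <= rec.reciprocity <= 1.0

    def test_prediction_nondecreasing_in_delta(self):
        trial = TrialSpec(1, "unambiguous", 10, 2, "low")
        returns = [
            simulate_return(
                AgentParams(d, 0.5, 0.0), trial, np.random.default_rng(0)
            ).returned
            for d in np.linspace(0, 1, 21)
        ]
        assert all(b >= a for a, b in zip(returns, returns[1:]))
        assert returns[0] == 0.0
        assert returns[-1] == pytest.approx(trial.pot)

    def test_ambiguous_uses_resolved_endowment(self):
        agent = AgentParams(0.5, 1.0, 0.0)  # HAT: acts on smallest candidate
        trial = amb_trial(7, (10, 20, 50))
        rec = simulate_return(agent, trial, np.random.default_rng(0))
        assert rec.resolved_endowment == 10.0
        # Eq 1 at E=10, I=7: (10-7+28)*0.5 - 3 = 12.5
        assert rec.returned == pytest.approx(12.5)


class TestSimulateCohort:
    def test_cohort_shape(self, session_design):
        mix = [
            (archetype_agent("MT", 0.5, 0.05), 24),
            (archetype_agent("LAT", 0.65, 0.05), 8),
            (archetype_agent("HAT", 0.55, 0.05), 2),
        ]
        choices, truth = simulate_cohort(mix, session_design, seed=0)
        assert len(truth) == 34
        assert len(choices) == 34 * 120
        assert truth["strategy_label"].value_counts().to_dict() == {
            "MT": 24,
            "LAT": 8,
            "HAT": 2,
        }

    def test_determinism(self, session_design):
        mix = [(archetype_agent("MT", 0.5, 0.0), 1)]
        a, _ = simulate_cohort(mix, session_design, seed=4)
        b, _ = simulate_cohort(mix, session_design, seed=4)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_labels_partition_cohort(self, session_design):
        mix = [(archetype_agent(s, 0.6, 0.0), 3) for s in ("HAT", "LAT", "MT", "HR")]
        _, truth = simulate_cohort(mix, session_design, seed=0)
        assert truth["participant_id"].is_unique
        assert truth["strategy_label"].value_counts().sum() == 12

    def test_empty_mixture_rejected(self, session_design):
        with pytest.raises(ValueError):
            simulate_cohort([], session_design, seed=0)

    def test_substreams_stable_under_cohort_growth(self, session_design):
        mix_small = [(archetype_agent("MT", 0.5, 0.05), 2)]
        mix_big = [
            (archetype_agent("MT", 0.5, 0.05), 2),
            (archetype_agent("LAT", 0.65, 0.05), 2),
        ]
        small, _ = simulate_cohort(mix_small, session_design, seed=9)
        big, _ = simulate_cohort(mix_big, session_design, seed=9)
        first_two = big[big.participant_id.isin(["P001", "P002"])].reset_index(drop=True)
        pd.testing.assert_frame_equal(small, first_two)


class TestBonusPayment:
    def test_full_endowment_kept_pot(self):
        # E=10, I=10, returned 0: payout 40, total 40 -> full 16 EUR bonus
        trial = TrialSpec(1, "unambiguous", 10, 10, "high")
        rec = ChoiceRecord("P1", 1, returned=0.0, pot=40.0, reciprocity=0.0)
        assert bonus_payment(rec, trial) == pytest.approx(16.0)

    def test_everything_returned(self):
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        rec = ChoiceRecord("P1", 1, returned=20.0, pot=20.0, reciprocity=1.0)
        assert bonus_payment(rec, trial) == 0.0

    def test_hand_arithmetic(self):
        # E=10, I=5, returned 10: (20-10) / (5+20) * 16 = 6.4
        trial = TrialSpec(1, "unambiguous", 10, 5, "medium")
        rec = ChoiceRecord("P1", 1, returned=10.0, pot=20.0, reciprocity=0.5)
        assert bonus_payment(rec, trial) == pytest.approx(6.4)


class TestChoiceRecord:
    def test_returned_bounded_by_pot(self):
        with pytest.raises(ValueError):
            ChoiceRecord("P1", 1, returned=21.0, pot=20.0, reciprocity=1.05)
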