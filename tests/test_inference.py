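import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trustgame.agents import AgentParams, simulate_cohort
from trustgame.design import AMBIGUOUS_BLOCKS
from trustgame.inference import (
    EXACT_INVERSE,
    PRINTED_EQ2,
    SingularInversionError,
    ambiguous_table,
    infer_endowments,
    invert_exact_unclamped,
    invert_return_exact,
    invert_return_printed,
    snap_candidate,
)
from trustgame.reciprocity import fit_delta_cohort, predict_return


class TestExactInverse:
    def test_hand_example(self):
        inf = invert_return_exact(7.5, 5, 0.5, (5, 10, 20))
        assert inf.e_inferred == pytest.approx(10.0)
        assert inf.snapped_candidate == 10.0
        assert not inf.censored

    def test_round_trip_identity(self):
        for E, I, delta in [(10, 5, 0.5), (20, 4, 0.7), (50, 10, 0.8), (5, 2, 0.6)]:
            r2 = predict_return(E, I, 4, delta)
            assert r2 > 0
            assert invert_exact_unclamped(r2, I, delta) == pytest.approx(E, abs=1e-9)

    def test_round_trip_exhaustive_over_printed_blocks(self):
        # all candidate endowments x integer investments x a delta grid,
        # restricted to trials where the forward model is not censored
        deltas = np.round(np.arange(0.05, 0.96, 0.05), 2)
        checked = 0
        for _, investments, candidates in AMBIGUOUS_BLOCKS:
            for I, E, delta in itertools.product(investments, candidates, deltas):
                if I > E:
                    continue
                r2 = predict_return(E, I, 4, float(delta))
                if r2 <= 0:
                    continue
                assert invert_exact_unclamped(r2, I, float(delta)) == pytest.approx(
                    E, abs=1e-9
                )
                checked += 1
        assert checked > 100

    def test_censored_zero_return(self):
        # Eq 1 predicts 0 for all E >= I(1+3*delta)/(1-delta) ~ 5.43
        inf = invert_return_exact(0.0, 2, 0.3, (2, 5, 10))
        assert inf.censored
        assert inf.e_inferred == 10.0
        assert inf.snapped_candidate == 10.0

    def test_singular_delta(self):
        with pytest.raises(SingularInversionError):
            invert_return_exact(5.0, 2, 1.0, (2, 5, 10))
        with pytest.raises(SingularInversionError):
            invert_exact_unclamped(5.0, 2, 1.0)

    def test_clamped_to_candidate_range(self):
        # huge return implies E below the smallest candidate -> clamped up
        inf = invert_return_exact(8.0, 2, 0.5, (2, 5, 10))
        assert 2.0 <= inf.e_inferred <= 10.0

    @given(
        delta=st.floats(min_value=0.05, max_value=0.95),
        I=st.integers(min_value=1, max_value=10),
        r_lo=st.floats(min_value=0.1, max_value=20),
        r_hi=st.floats(min_value=0.1, max_value=20),
    )
    @settings(max_examples=100)
    def test_unclamped_inverse_decreasing_in_r2(self, delta, I, r_lo, r_hi):
        lo, hi = sorted([r_lo, r_hi])
        if hi - lo < 1e-9:
            return
        e_lo = invert_exact_unclamped(lo, I, delta)
        e_hi = invert_exact_unclamped(hi, I, delta)
        assert e_hi < e_lo


class TestPrintedEq2:
    def test_hand_example_shows_discrepancy(self):
        # printed formula gives 0 where the exact inverse gives 10
        assert invert_return_printed(7.5, 5, 0.5, 20) == pytest.approx(0.0)
        assert invert_return_exact(7.5, 5, 0.5, (5, 10, 20)).e_inferred == 10.0

    def test_degenerate_no_investment_limit(self):
        assert invert_return_printed(0.0, 0, 0.5, 10) == 0.0

    def test_difference_is_I_over_delta_minus_one(self):
        for I in (2, 4, 5, 7, 10):
            for delta in np.arange(0.05, 0.96, 0.1):
                for r2 in (0.5, 3.0, 12.0):
                    printed = (r2 - 3 * I * delta) / (delta - 1)
                    exact = invert_exact_unclamped(r2, I, float(delta))
                    assert printed - exact == pytest.approx(
                        I / (delta - 1), rel=1e-9
                    )

    def test_singular(self):
        with pytest.raises(SingularInversionError):
            invert_return_printed(5.0, 2, 1.0, 10)


class TestSnapping:
    def test_nearest(self):
        assert snap_candidate(8.4, (2, 5, 10)) == 10.0
        assert snap_candidate(6.0, (2, 5, 10)) == 5.0

    def test_tie_breaks_smaller(self):
        assert snap_candidate(7.5, (5, 10, 20)) == 5.0

    def test_interior_value_unaffected_by_clamp(self):
        inf = invert_return_exact(7.5, 5, 0.5, (5, 10, 20))
        assert inf.snapped_candidate == snap_candidate(10.0, (5, 10, 20))


@pytest.fixture(scope="module")
def noiseless_run(session_design):
    agent = AgentParams(delta=0.5, tau=0.5, psi=0.0, label="MT")
    choices, _ = simulate_cohort([(agent, 2)], session_design, seed=0)
    fits = fit_delta_cohort(choices)
    return choices, fits


class TestBatchInference:
    def test_recovers_resolved_endowments(self, session_design, noiseless_run):
        choices, fits = noiseless_run
        inferences = infer_endowments(choices, fits, session_design)
        merged = inferences.merge(
            choices[["participant_id", "trial_index", "resolved_endowment"]],
            on=["participant_id", "trial_index"],
        )
        ok = ~merged["censored"]
        assert ok.mean() > 0.9
        assert (
            merged.loc[ok, "snapped_candidate"]
            == merged.loc[ok, "resolved_endowment"]
        ).all()

    def test_censored_rows_get_largest_candidate(self, session_design, noiseless_run):
        choices, fits = noiseless_run
        inferences = infer_endowments(choices, fits, session_design)
        censored = inferences[inferences.censored]
        if len(censored):
            trial_map = {t.trial_index: t for t in session_design.trials}
            for row in censored.itertuples(index=False):
                assert row.e_inferred == trial_map[row.trial_index].e_max

    def test_printed_method_column(self, session_design, noiseless_run):
        choices, fits = noiseless_run
        inferences = infer_endowments(
            choices, fits, session_design, method=PRINTED_EQ2
        )
        assert (inferences["method"] == PRINTED_EQ2).all()

    def test_unknown_method(self, session_design, noiseless_run):
        choices, fits = noiseless_run
        with pytest.raises(ValueError):
            infer_endowments(choices, fits, session_design, method="nope")

    def test_singular_participant_flagged(self, session_design):
        agent = AgentParams(delta=1.0, tau=0.5, psi=0.0)
        choices, _ = simulate_cohort([(agent, 1)], session_design, seed=0)
        fits = fit_delta_cohort(choices)
        assert fits["delta_hat"].iloc[0] == 1.0
        inferences = infer_endowments(choices, fits, session_design)
        assert inferences["singular"].all()
        assert inferences["e_inferred"].isna().all()

    def test_ambiguous_table_schema(self, session_design, noiseless_run):
        choices, fits = noiseless_run
        inferences = infer_endowments(choices, fits, session_design)
        table = ambiguous_table(session_design, inferences)
        assert len(table) == 2 * 80
        assert {"investment", "cand1", "cand2", "cand3", "observed_candidate"} <= set(
            table.columns
        )
        assert (table["cand1"] < table["cand2"]).all()
        assert (table["cand2"] < table["cand3"]).all()
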