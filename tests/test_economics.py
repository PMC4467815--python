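"""Discounting, cost/QALY accrual, incremental comparison and dominance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phoscea.decision_tree import Strategy
from phoscea.economics import (ArmResult, Dominance, arm_costs,
                               discount_stream, evaluate, incremental,
                               strategy_streams)
from phoscea.fixtures import _with_flat_rr
from phoscea.markov import run_strategy
from phoscea.parameters import DiscountTiming


def _arm(strategy, qalys, total_cost, ly=0.0):
    return ArmResult(strategy=strategy, life_years=ly, dialysis_free_years=0.0,
                     qalys=qalys, drug_cost=total_cost, dialysis_cost=0.0)


class TestDiscounting:
    def test_no_discount_is_plain_sum(self):
        assert discount_stream([100.0], 0.0) == 100.0

    def test_half_cycle_exponents(self):
        expected = 100 / 1.03 ** 0.5 + 100 / 1.03 ** 1.5
        assert discount_stream([100.0, 100.0], 0.03) == pytest.approx(expected, abs=1e-12)

    def test_end_cycle_exponents(self):
        expected = 100 / 1.03 + 100 / 1.03 ** 2
        assert discount_stream([100.0, 100.0], 0.03,
                               DiscountTiming.END_CYCLE) == pytest.approx(expected)

    def test_empty_stream(self):
        assert discount_stream([], 0.05) == 0.0

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=30),
           st.floats(0.001, 0.2))
    def test_discounting_never_gains(self, values, rate):
        assert discount_stream(values, rate) <= sum(values) + 1e-9

    def test_higher_rate_lowers_qalys_in_both_arms(self, base_params, base_result):
        res6 = evaluate(base_params.copy_with(**{"settings.discount_rate": 0.06}))
        assert res6.cb.qalys < base_result.cb.qalys
        assert res6.lc.qalys < base_result.lc.qalys
        res0 = evaluate(base_params.copy_with(**{"settings.discount_rate": 0.0}))
        assert res0.cb.qalys > base_result.cb.qalys


@pytest.fixture(scope="module")
def everyone_on_lc(base_params):
    """All patients respond to LC only and progress immediately:
    from cycle 2 on the whole cohort sits in dialysis on LC."""
    return _with_flat_rr(base_params, **{
        "efficacy.response_rate_cb_predialysis.value": 0.0,
        "efficacy.response_rate_cb_predialysis.ci_low": 0.0,
        "efficacy.response_rate_cb_dialysis.value": 0.0,
        "efficacy.response_rate_cb_dialysis.ci_low": 0.0,
        "efficacy.response_rate_lc_predialysis.value": 1.0,
        "efficacy.response_rate_lc_predialysis.ci_high": 1.0,
        "efficacy.response_rate_lc_dialysis.value": 1.0,
        "efficacy.response_rate_lc_dialysis.ci_high": 1.0,
        "epi.mortality_predialysis_annual": 0.0,
        "epi.mortality_dialysis_annual": 0.0,
        "epi.progression_annual.value": 1.0,
        "epi.progression_annual.ci_high": 1.0,
        "epi.sp_nonresponder_predialysis": 4.6,
        "epi.sp_nonresponder_dialysis": 4.6,
    })


class TestAccrual:
    def test_dialysis_lc_patient_year_qaly(self, everyone_on_lc):
        """One LC patient-year in dialysis: 0.61 - 0.072 x 0.04082."""
        streams = strategy_streams(
            run_strategy(everyone_on_lc, Strategy.LC_SECOND_LINE), everyone_on_lc)
        assert streams.qalys[2] == pytest.approx(0.61 - 0.072 * 0.04082, abs=1e-9)

    def test_predialysis_patient_year_qaly(self, base_params):
        p = _with_flat_rr(base_params, **{
            "epi.mortality_predialysis_annual": 0.0,
            "epi.progression_annual.value": 0.0,
            "epi.progression_annual.ci_low": 0.0})
        streams = strategy_streams(run_strategy(p, Strategy.CB_CONTINUED), p)
        assert streams.qalys[0] == pytest.approx(0.71, abs=1e-12)

    def test_dialysis_lc_patient_year_drug_cost(self, everyone_on_lc):
        streams = strategy_streams(
            run_strategy(everyone_on_lc, Strategy.LC_SECOND_LINE), everyone_on_lc)
        assert streams.drug_cost[2] == pytest.approx(
            everyone_on_lc.lc_annual_cost("dialysis"), abs=1e-9)

    def test_identical_traces_have_no_attributable_dialysis_cost(self, base_params):
        streams = strategy_streams(
            run_strategy(base_params, Strategy.CB_CONTINUED), base_params)
        _, dial = arm_costs(streams, base_params, reference=streams)
        np.testing.assert_allclose(dial, 0.0, atol=1e-12)

    def test_horizon_mismatch_rejected(self, base_params):
        streams = strategy_streams(
            run_strategy(base_params, Strategy.CB_CONTINUED), base_params)
        short = evaluate(base_params.copy_with(
            **{"settings.horizon_years": 5})).cb_streams
        with pytest.raises(ValueError):
            arm_costs(streams, base_params, reference=short)


class TestIncremental:
    def test_published_nmb_reconstruction(self):
        """dC = -3,875k, dQALY = 73.88 at 30,000/QALY -> NMB ~ 6,091-6,092k,
        dominant."""
        cb = _arm(Strategy.CB_CONTINUED, qalys=4579.0, total_cost=5_044_000.0)
        lc = _arm(Strategy.LC_SECOND_LINE, qalys=4579.0 + 73.88,
                  total_cost=5_044_000.0 - 3_875_000.0)
        ce = incremental(cb, lc, 30_000.0)
        assert ce.dominance == Dominance.DOMINANT
        assert ce.icer_per_qaly == "dominant"
        assert ce.nmb == pytest.approx(6_091_400, abs=1e3)

    def test_tradeoff_icer(self):
        cb = _arm(Strategy.CB_CONTINUED, qalys=0.0, total_cost=0.0)
        lc = _arm(Strategy.LC_SECOND_LINE, qalys=73.88, total_cost=3_336_000.0)
        ce = incremental(cb, lc, 30_000.0)
        assert ce.dominance == Dominance.TRADEOFF_NE
        assert ce.icer_per_qaly == pytest.approx(45_154, abs=1)

    def test_no_difference(self):
        a = _arm(Strategy.CB_CONTINUED, 1.0, 1.0)
        b = _arm(Strategy.LC_SECOND_LINE, 1.0, 1.0)
        ce = incremental(a, b, 30_000.0)
        assert ce.dominance == Dominance.NO_DIFFERENCE

    def test_zero_effect_nonzero_cost_has_undefined_icer(self):
        a = _arm(Strategy.CB_CONTINUED, 1.0, 0.0)
        b = _arm(Strategy.LC_SECOND_LINE, 1.0, 10.0)
        assert "undefined" in incremental(a, b, 30_000.0).icer_per_qaly

    @given(st.floats(-1e6, 1e6), st.floats(-100, 100))
    def test_dominance_quadrants(self, d_cost, d_qaly):
        cb = _arm(Strategy.CB_CONTINUED, qalys=100.0, total_cost=1e6)
        lc = _arm(Strategy.LC_SECOND_LINE, qalys=100.0 + d_qaly,
                  total_cost=1e6 + d_cost)
        ce = incremental(cb, lc, 30_000.0)
        dc, dq = ce.delta_cost, ce.delta_qalys
        if dc < 0 and dq > 0:
            assert ce.dominance == Dominance.DOMINANT
        elif dc > 0 and dq < 0:
            assert ce.dominance == Dominance.DOMINATED
        elif dc == 0 and dq == 0:
            assert ce.dominance == Dominance.NO_DIFFERENCE
        elif dc >= 0 and dq >= 0:
            assert ce.dominance == Dominance.TRADEOFF_NE
        else:
            assert ce.dominance == Dominance.TRADEOFF_SW
        # NMB at a zero threshold is minus the incremental cost
        assert incremental(cb, lc, 0.0).nmb == pytest.approx(-dc, abs=1e-9)

    @given(st.floats(0, 1e5), st.floats(0, 1e5), st.floats(0, 1))
    def test_nmb_linear_in_lambda(self, lam1, lam2, w):
        cb = _arm(Strategy.CB_CONTINUED, qalys=10.0, total_cost=5.0)
        lc = _arm(Strategy.LC_SECOND_LINE, qalys=12.0, total_cost=9.0)
        lam = w * lam1 + (1 - w) * lam2
        mix = w * incremental(cb, lc, lam1).nmb + (1 - w) * incremental(cb, lc, lam2).nmb
        assert incremental(cb, lc, lam).nmb == pytest.approx(mix, rel=1e-9, abs=1e-6)


class TestDialysisFreeYears:
    def test_identical_policies_gain_nothing(self, base_params):
        from phoscea.economics import incremental_dialysis_free_years
        s = strategy_streams(run_strategy(base_params, Strategy.CB_CONTINUED), base_params)
        assert incremental_dialysis_free_years(s, s, base_params) == 0.0

    def test_no_progression_advantage_no_gain(self, base_params):
        """When responders keep the non-responder SP, LC delays nothing."""
        p = base_params.copy_with(**{
            "epi.sp_responder": base_params.epi.sp_nonresponder_predialysis})
        res = evaluate(p)
        assert res.dialysis_free_years_gained == pytest.approx(0.0, abs=1e-6)
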