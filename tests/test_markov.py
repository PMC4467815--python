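"""Cohort engine: transition arithmetic, conservation, absorption,
half-cycle correction and closed-form survival agreement."""

import numpy as np
import pytest

from phoscea.decision_tree import Strategy, build_arms
from phoscea.fixtures import _with_flat_rr, closed_form_life_years
from phoscea.markov import (build_transitions, half_cycle_correct,
                            mortality_probability, progression_probability,
                            run_cohort, run_strategy)
from phoscea.parameters import RRApplication, Stage


class TestRiskAdjustment:
    def test_identity_at_rr_one(self):
        assert mortality_probability(0.123, 1.0) == pytest.approx(0.123)

    def test_rate_domain(self):
        # 1 - 0.877^1.90, evaluated by hand
        assert mortality_probability(0.123, 1.90) == pytest.approx(
            1 - 0.877 ** 1.90, abs=1e-12)
        assert mortality_probability(0.123, 1.90) == pytest.approx(0.2209, abs=5e-4)

    def test_multiplicative_switch(self):
        assert mortality_probability(
            0.123, 1.90, RRApplication.MULTIPLICATIVE) == pytest.approx(0.2337, abs=1e-6)

    def test_capped_at_one(self):
        assert mortality_probability(0.9, 100, RRApplication.MULTIPLICATIVE) == 1.0

    def test_progression_at_target_is_base_rate(self):
        assert progression_probability(0.143, 4.6, 4.6, 1.19) == pytest.approx(0.143)
        assert progression_probability(0.143, 3.0, 4.6, 1.19) == pytest.approx(0.143)

    def test_progression_above_target(self):
        expected = 1 - 0.857 ** (1.19 ** 1.1)   # SP 5.7 vs target 4.6
        assert progression_probability(0.143, 5.7, 4.6, 1.19) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_base_stays_zero(self):
        assert progression_probability(0.0, 9.0, 4.6, 1.19) == 0.0


class TestTransitions:
    def test_flat_tables_reproduce_base_rates(self, base_params):
        p = _with_flat_rr(base_params)
        for arm in build_arms(p, Strategy.CB_CONTINUED):
            tr = build_transitions(arm, p)
            assert tr.p_die_predialysis == pytest.approx(0.123)
            assert all(d == pytest.approx(p.epi.mortality_dialysis_annual)
                       for d in tr.p_die_dialysis)

    def test_nonresponder_uses_stratum_of_its_sp(self, base_params):
        arm = build_arms(base_params, Strategy.CB_CONTINUED)[1]   # SP 5.7
        tr = build_transitions(arm, base_params)
        assert tr.p_die_predialysis == pytest.approx(1 - 0.877 ** 1.90)


class TestEngine:
    def test_death_first_hand_computed_first_row(self, base_params):
        """p_die=0.123, p_prog=0.143, death first:
        row 1 = (0.877*0.857, 0.877*0.143, 0.123)."""
        p = _with_flat_rr(base_params, **{
            "epi.sp_nonresponder_predialysis": 4.6,
            "epi.sp_nonresponder_dialysis": 4.6})
        arm = build_arms(p, Strategy.CB_CONTINUED)[1]
        tr = run_cohort(arm, p)
        np.testing.assert_allclose(
            tr.three_state[1], [0.751589, 0.125411, 0.123], atol=1e-9)

    def test_all_zero_probabilities_freeze_the_cohort(self, base_params):
        p = _with_flat_rr(base_params, **{
            "epi.mortality_predialysis_annual": 0.0,
            "epi.mortality_dialysis_annual": 0.0,
            "epi.progression_annual.value": 0.0,
            "epi.progression_annual.ci_low": 0.0})
        arm = build_arms(p, Strategy.CB_CONTINUED)[0]
        tr = run_cohort(arm, p)
        assert (tr.three_state[:, 0] == 1.0).all()

    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_conservation_and_absorption(self, base_params, strategy):
        """Rows sum to 1 within 1e-9 over 40 cycles; death never shrinks."""
        for trace in run_strategy(base_params, strategy).traces:
            sums = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert (np.diff(trace.dead) >= -1e-15).all()

    def test_certain_dialysis_death_empties_dialysis(self, base_params):
        p = base_params.copy_with(**{"epi.mortality_dialysis_annual": 1.0})
        arm = build_arms(p, Strategy.CB_CONTINUED)[1]
        tr = run_cohort(arm, p)
        # dialysis occupancy each cycle equals that cycle's inflow only
        np.testing.assert_allclose(
            tr.occupancy[1:, 1:-1], tr.dialysis_inflow[1:], atol=1e-12)

    def test_mortality_monotonicity(self, base_params):
        """Raising baseline predialysis mortality weakly decreases life
        years; raising progression weakly decreases dialysis-free years."""
        from phoscea.economics import evaluate
        res = evaluate(base_params)
        worse = evaluate(base_params.copy_with(
            **{"epi.mortality_predialysis_annual": 0.2}))
        assert worse.cb.life_years <= res.cb.life_years
        faster = evaluate(base_params.copy_with(**{
            "epi.progression_annual.value": 0.15,
            "epi.progression_annual.ci_high": 0.15}))
        assert faster.cb.dialysis_free_years <= res.cb.dialysis_free_years


class TestHalfCycle:
    def test_mean_of_adjacent_rows(self):
        occ = np.array([[1.0, 0.0, 0.0], [0.8, 0.1, 0.1]])
        np.testing.assert_allclose(half_cycle_correct(occ)[0], [0.9, 0.05, 0.05])

    def test_constant_trace_is_fixed_point(self):
        occ = np.tile([0.5, 0.3, 0.2], (6, 1))
        np.testing.assert_allclose(half_cycle_correct(occ), occ[1:])

    def test_matches_trapezoid_rule(self):
        rng = np.random.default_rng(0)
        occ = rng.random((11, 3))
        corrected = half_cycle_correct(occ)
        np.testing.assert_allclose(corrected.sum(axis=0),
                                   np.trapezoid(occ, axis=0), atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            half_cycle_correct(np.array([[1.0, 0.0, 0.0]]))

    @pytest.mark.parametrize("p_die", [0.05, 0.123, 0.5])
    def test_closed_form_geometric_survival(self, base_params, p_die):
        """Constant death probability, no progression, no discounting:
        engine life years equal the geometric closed form to 1e-9."""
        p = _with_flat_rr(base_params, **{
            "epi.mortality_predialysis_annual": p_die,
            "epi.progression_annual.value": 0.0,
            "epi.progression_annual.ci_low": 0.0,
            "settings.discount_rate": 0.0})
        arm = build_arms(p, Strategy.CB_CONTINUED)[0]
        tr = run_cohort(arm, p)
        ly = tr.corrected_occupancy[:, 0].sum()
        assert ly == pytest.approx(
            closed_form_life_years(p_die, p.settings.horizon_years), abs=1e-9)
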