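"""Discounted costs, life years, dialysis-free years and QALYs per
strategy, and incremental cost-effectiveness (ICER, dominance, net
monetary benefit).

All streams are indexed by cycle t = 1..H and valued on half-cycle-
corrected occupancy; discounting uses exponent t - 0.5 by default so
that accrual timing matches the correction (a plain end-of-cycle
exponent is available through ``settings.discount_timing``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .decision_tree import Strategy, lc_trial_year_cost_weight
from .markov import StrategyTrace, half_cycle_correct, run_strategy
from .parameters import (DiscountTiming, FutureDialysisCostMode, ModelParameters,
                         Stage)


def discount_factors(n_cycles: int, rate: float,
                     timing: DiscountTiming = DiscountTiming.HALF_CYCLE) -> np.ndarray:
    """Discount factors for cycles 1..n_cycles."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    t = np.arange(1, n_cycles + 1, dtype=float)
    if timing == DiscountTiming.HALF_CYCLE:
        t = t - 0.5
    return (1.0 + rate) ** (-t)


def discount_stream(values: Sequence[float], rate: float,
                    timing: DiscountTiming = DiscountTiming.HALF_CYCLE) -> float:
    """Present value of a per-cycle stream (cycle 1 first)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    return float(values @ discount_factors(values.size, rate, timing))


@dataclass
class StrategyStreams:
    """Undiscounted per-cycle streams for one strategy, per member of the
    entering cohort (multiply by cohort size for cohort totals)."""

    strategy: Strategy
    predialysis: np.ndarray    # corrected occupancy-years in predialysis
    dialysis: np.ndarray       # corrected occupancy-years in dialysis
    drug_cost: np.ndarray      # € per cycle
    qalys: np.ndarray          # QALYs per cycle


@dataclass
class ArmResult:
    """Discounted totals for one strategy, scaled to the cohort."""

    strategy: Strategy
    life_years: float
    dialysis_free_years: float   # discounted predialysis occupancy-years
    qalys: float
    drug_cost: float
    dialysis_cost: float

    @property
    def total_cost(self) -> float:
        return self.drug_cost + self.dialysis_cost


class Dominance(str, enum.Enum):
    DOMINANT = "dominant"          # cheaper and more effective
    DOMINATED = "dominated"        # dearer and less effective
    TRADEOFF_NE = "tradeoff_NE"    # dearer, more effective: ICER meaningful
    TRADEOFF_SW = "tradeoff_SW"    # cheaper, less effective
    NO_DIFFERENCE = "no_difference"


@dataclass
class CEResult:
    """Incremental comparison of the LC strategy against continued CB."""

    delta_cost: float
    delta_qalys: float
    delta_ly: float
    dominance: Dominance
    icer_per_qaly: float | str
    icer_per_ly: float | str
    nmb: float
    threshold_lambda: float


def strategy_streams(st: StrategyTrace, params: ModelParameters) -> StrategyStreams:
    """Occupancy-year, drug-cost and QALY streams for one strategy.

    Drug costs charge each compartment's corrected occupancy at its
    regimen's annual cost. Patients who trial LC and switch back incur
    the LC-CB cost difference for the trial fraction of their first year
    in a stage, charged on the mass entering that stage (the whole arm in
    cycle 1 for predialysis; the per-cycle dialysis inflow thereafter).
    The vomiting disutility applies to occupancy maintained on LC.
    """
    settings, util = params.settings, params.utilities
    H = settings.horizon_years
    lc_frac, _cb_frac = lc_trial_year_cost_weight(settings.lc_trial_weeks)
    cb_pre = params.cb_annual_cost(Stage.PREDIALYSIS)
    cb_dial = params.cb_annual_cost(Stage.DIALYSIS)
    lc_pre = params.lc_annual_cost(Stage.PREDIALYSIS)
    lc_dial = params.lc_annual_cost(Stage.DIALYSIS)

    pre_years = np.zeros(H)
    dial_years = np.zeros(H)
    drug = np.zeros(H)
    qaly = np.zeros(H)

    for arm, tr in zip(st.arms, st.traces):
        w = arm.fraction_of_cohort
        if w == 0:
            continue
        corr = tr.corrected_occupancy          # (H, 2+K)
        pre = corr[:, 0]
        dials = corr[:, 1:-1]                  # per dialysis compartment
        pre_years += w * pre
        dial_years += w * dials.sum(axis=1)

        # drug costs: predialysis
        pre_cost_rate = lc_pre if arm.on_lc else cb_pre
        drug += w * pre * pre_cost_rate
        if arm.lc_trial and lc_frac > 0:
            drug[0] += w * lc_frac * (lc_pre - cb_pre)

        # drug costs: dialysis compartments
        for k, d_arm in enumerate(tr.dialysis_arms):
            rate = lc_dial if d_arm.on_lc else cb_dial
            drug += w * dials[:, k] * rate
            if d_arm.lc_trial and lc_frac > 0:
                drug += w * tr.dialysis_inflow[1:, k] * lc_frac * (lc_dial - cb_dial)

        # QALYs
        q = pre * util.utility_predialysis + dials.sum(axis=1) * util.utility_dialysis
        if arm.on_lc:
            q = q - pre * util.vomit_rate(Stage.PREDIALYSIS) * util.vomit_decrement
        for k, d_arm in enumerate(tr.dialysis_arms):
            if d_arm.on_lc:
                q = q - dials[:, k] * util.vomit_rate(Stage.DIALYSIS) * util.vomit_decrement
        qaly += w * q

    return StrategyStreams(strategy=st.strategy, predialysis=pre_years,
                           dialysis=dial_years, drug_cost=drug, qalys=qaly)


def arm_costs(own: StrategyStreams, params: ModelParameters,
              reference: Optional[StrategyStreams] = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (drug_cost, dialysis_cost) streams for one strategy.

    Under ``attributable_only``, dialysis care in a strategy's added
    life years is an unrelated future cost and excluded: each cycle, a
    strategy is charged only for dialysis occupancy in excess of what
    the comparator's dialysis share among its own survivors would imply
    for this strategy's surviving population, floored at zero. This
    isolates the binder-attributable (progression-timing) dialysis use
    from dialysis that accrues merely because patients live longer.
    Under ``full`` every dialysis occupancy-year is charged in both
    strategies.
    """
    settings = params.settings
    unit = settings.dialysis_annual_cost
    if settings.future_dialysis_cost_mode == FutureDialysisCostMode.FULL:
        dial_cost = own.dialysis * unit
    else:
        if reference is None:
            dial_cost = np.zeros_like(own.dialysis)
        else:
            if reference.dialysis.shape != own.dialysis.shape:
                raise ValueError("strategy traces must share the same horizon")
            own_alive = own.predialysis + own.dialysis
            ref_alive = reference.predialysis + reference.dialysis
            ref_share = np.divide(reference.dialysis, ref_alive,
                                  out=np.zeros_like(ref_alive),
                                  where=ref_alive > 1e-12)
            excess = own.dialysis - ref_share * own_alive
            # occupancies are O(1): excesses at float-noise level are zero
            dial_cost = np.where(excess > 1e-12, excess, 0.0) * unit
    return own.drug_cost, dial_cost


def arm_result(own: StrategyStreams, params: ModelParameters,
               reference: Optional[StrategyStreams] = None) -> ArmResult:
    """Discounted cohort totals for one strategy."""
    settings = params.settings
    rate, timing = settings.discount_rate, settings.discount_timing
    n = settings.cohort_size
    drug_stream, dial_stream = arm_costs(own, params, reference)
    ly = discount_stream(own.predialysis + own.dialysis, rate, timing)
    return ArmResult(
        strategy=own.strategy,
        life_years=n * ly,
        dialysis_free_years=n * discount_stream(own.predialysis, rate, timing),
        qalys=n * discount_stream(own.qalys, rate, timing),
        drug_cost=n * discount_stream(drug_stream, rate, timing),
        dialysis_cost=n * discount_stream(dial_stream, rate, timing),
    )


def incremental_dialysis_free_years(lc: StrategyStreams, cb: StrategyStreams,
                                    params: ModelParameters) -> float:
    """Discounted dialysis-free years gained by the LC strategy: per-cycle
    excess predialysis occupancy over the CB strategy, floored at zero,
    scaled to the cohort."""
    settings = params.settings
    excess = np.maximum(0.0, lc.predialysis - cb.predialysis)
    return settings.cohort_size * discount_stream(
        excess, settings.discount_rate, settings.discount_timing)


def incremental(cb: ArmResult, lc: ArmResult, threshold_lambda: float) -> CEResult:
    """Incremental cost-effectiveness of LC second line versus continued CB.

    NMB = lambda * dQALY - dCost, so cost savings add to the benefit.
    ICERs are reported as numbers only in the trade-off quadrants; under
    dominance the quadrant label is carried instead.
    """
    d_cost = lc.total_cost - cb.total_cost
    d_qaly = lc.qalys - cb.qalys
    d_ly = lc.life_years - cb.life_years
    nmb = threshold_lambda * d_qaly - d_cost

    if d_cost == 0 and d_qaly == 0:
        dom = Dominance.NO_DIFFERENCE
    elif d_cost < 0 and d_qaly > 0:
        dom = Dominance.DOMINANT
    elif d_cost > 0 and d_qaly < 0:
        dom = Dominance.DOMINATED
    elif d_qaly >= 0 and d_cost >= 0:
        dom = Dominance.TRADEOFF_NE
    else:
        dom = Dominance.TRADEOFF_SW

    def ratio(delta_effect: float) -> float | str:
        if dom in (Dominance.DOMINANT, Dominance.DOMINATED, Dominance.NO_DIFFERENCE):
            return dom.value
        if delta_effect == 0:
            return "undefined (zero effect difference)"
        return d_cost / delta_effect

    return CEResult(delta_cost=d_cost, delta_qalys=d_qaly, delta_ly=d_ly,
                    dominance=dom, icer_per_qaly=ratio(d_qaly),
                    icer_per_ly=ratio(d_ly), nmb=nmb,
                    threshold_lambda=threshold_lambda)


@dataclass
class ComparisonResult:
    """Full deterministic model evaluation: both strategies plus the
    incremental comparison."""

    cb: ArmResult
    lc: ArmResult
    ce: CEResult
    dialysis_free_years_gained: float
    cb_streams: StrategyStreams
    lc_streams: StrategyStreams


def evaluate(params: ModelParameters) -> ComparisonResult:
    """Run the complete pipeline: decision tree, cohort traces, costing
    and the incremental comparison."""
    st_cb = run_strategy(params, Strategy.CB_CONTINUED)
    st_lc = run_strategy(params, Strategy.LC_SECOND_LINE)
    s_cb = strategy_streams(st_cb, params)
    s_lc = strategy_streams(st_lc, params)
    res_cb = arm_result(s_cb, params, reference=s_lc)
    res_lc = arm_result(s_lc, params, reference=s_cb)
    ce = incremental(res_cb, res_lc, params.settings.threshold_lambda)
    dfy = incremental_dialysis_free_years(s_lc, s_cb, params)
    return ComparisonResult(cb=res_cb, lc=res_lc, ce=ce,
                            dialysis_free_years_gained=dfy,
                            cb_streams=s_cb, lc_streams=s_lc)
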