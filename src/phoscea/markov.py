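"""Annual-cycle cohort engine over three health states — predialysis,
dialysis, death — with serum-phosphorus-stratified relative risks on
mortality and progression, a 40-year cap and half-cycle correction.

Each predialysis treatment arm is run as its own sub-cohort. Because the
dialysis population inside an arm is itself a mixture of response
subgroups (response is re-evaluated on entry to dialysis), the engine
tracks one compartment per dialysis arm internally and aggregates to the
three reported states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import Strategy, Subgroup, TreatmentArm, build_arms
from .parameters import CompetingRisk, ModelParameters, RRApplication, Stage


def mortality_probability(base_rate: float, rr: float,
                          mode: RRApplication = RRApplication.RATE_DOMAIN) -> float:
    """Annual death probability after applying a relative risk.

    Rate-domain mode treats the RR as a hazard ratio on the annual
    probability, p' = 1 - (1-p)^RR; multiplicative mode uses p*RR. Both
    are capped at 1.
    """
    if not 0 <= base_rate <= 1:
        raise ValueError(f"base_rate must be in [0, 1], got {base_rate}")
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    if mode == RRApplication.MULTIPLICATIVE:
        return min(1.0, base_rate * rr)
    return min(1.0, 1.0 - (1.0 - base_rate) ** rr)


def progression_probability(base_rate: float, sp: float, sp_target: float,
                            rr_per_mgdl: float,
                            mode: RRApplication = RRApplication.RATE_DOMAIN) -> float:
    """Annual progression (predialysis -> dialysis) probability.

    The progression relative risk compounds per mg/dL of SP above target:
    rr = rr_per_mgdl ** max(0, sp - sp_target), then applied as in
    :func:`mortality_probability`. At or below target the base rate is
    returned unchanged.
    """
    excess = max(0.0, sp - sp_target)
    rr = rr_per_mgdl ** excess
    return mortality_probability(base_rate, rr, mode)


@dataclass(frozen=True)
class TransitionProbs:
    """Per-cycle transition probabilities for one arm's predialysis state
    and the dialysis death probabilities of the strategy's dialysis arms."""

    p_die_predialysis: float
    p_progress: float
    p_die_dialysis: tuple[float, ...]  # one per dialysis arm


def build_transitions(arm: TreatmentArm, params: ModelParameters) -> TransitionProbs:
    """Transition probabilities implied by an arm's representative SP."""
    mode = params.settings.rr_application
    epi = params.epi
    rr_mort = params.mortality_rr(Stage.PREDIALYSIS, arm.sp)
    p_die = mortality_probability(epi.mortality_predialysis_annual, rr_mort, mode)
    p_prog = progression_probability(
        epi.progression_annual.value, arm.sp,
        params.settings.sp_target_for(Stage.PREDIALYSIS),
        epi.rr_progression_per_mgdl.value, mode)
    dial_arms = build_arms(params, arm.strategy, Stage.DIALYSIS)
    p_die_dial = tuple(
        mortality_probability(epi.mortality_dialysis_annual,
                              params.mortality_rr(Stage.DIALYSIS, d.sp), mode)
        for d in dial_arms)
    return TransitionProbs(p_die_predialysis=p_die, p_progress=p_prog,
                           p_die_dialysis=p_die_dial)


def competing_risk_split(p_die: float, p_prog: float,
                         mode: CompetingRisk) -> tuple[float, float]:
    """Resolve death and progression competing within one predialysis
    cycle into exit probabilities that sum to at most one.

    ``death_first`` applies death first and progression to survivors;
    ``independent_renormalized`` treats them as independent and rescales
    only if their sum exceeds one.
    """
    if mode == CompetingRisk.DEATH_FIRST:
        return p_die, (1.0 - p_die) * p_prog
    total = p_die + p_prog
    scale = 1.0 / total if total > 1 else 1.0
    return p_die * scale, p_prog * scale


@dataclass
class CohortTrace:
    """State occupancy of one arm's sub-cohort over the horizon.

    ``occupancy`` holds fractions of the arm's entering population:
    column 0 is predialysis, columns 1..K the dialysis compartments (one
    per dialysis arm of the strategy), the last column death. Row t is
    the occupancy after t cycles (row 0 is the entering distribution).
    ``dialysis_inflow`` records the mass newly arriving in each dialysis
    compartment during each cycle (rows 1..H; row 0 unused).
    """

    arm: TreatmentArm
    dialysis_arms: list[TreatmentArm]
    occupancy: np.ndarray           # (H+1, 2+K)
    dialysis_inflow: np.ndarray     # (H+1, K)
    cycles: int

    # -- aggregated three-state views -------------------------------------

    @property
    def predialysis(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def dialysis(self) -> np.ndarray:
        return self.occupancy[:, 1:-1].sum(axis=1)

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, -1]

    @property
    def three_state(self) -> np.ndarray:
        return np.column_stack([self.predialysis, self.dialysis, self.dead])

    @property
    def corrected_occupancy(self) -> np.ndarray:
        """Half-cycle-corrected compartment occupancy for cycles 1..H."""
        return half_cycle_correct(self.occupancy)


def half_cycle_correct(occupancy: np.ndarray) -> np.ndarray:
    """Life-table half-cycle correction: the occupancy credited to cycle
    t is the mean of the raw occupancies at the cycle's start and end.

    Input has H+1 rows (cycle boundaries 0..H); output has H rows
    (cycles 1..H).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape[0] < 2:
        raise ValueError("half-cycle correction needs at least two boundary rows")
    return 0.5 * (occupancy[:-1] + occupancy[1:])


def run_cohort(arm: TreatmentArm, params: ModelParameters) -> CohortTrace:
    """Run one predialysis arm's sub-cohort for the full horizon.

    Competing risks within a predialysis cycle follow the configured
    ordering: under ``death_first`` the annual death probability applies
    first and progression only to survivors, so rows always sum to one
    without renormalization; the ``independent_renormalized`` variant
    applies both risks independently and rescales if they exceed one.
    Death is absorbing and no dialysis-to-predialysis transition exists.
    Mass progressing to dialysis is split across the strategy's dialysis
    arms by their entry fractions.
    """
    settings = params.settings
    horizon = settings.horizon_years
    trans = build_transitions(arm, params)
    dial_arms = build_arms(params, arm.strategy, Stage.DIALYSIS)
    split = np.array([d.fraction_of_cohort for d in dial_arms])
    if split.size and abs(split.sum() - 1.0) > 1e-9:
        raise ValueError("dialysis entry fractions must sum to 1")
    K = len(dial_arms)

    pre_to_dead, pre_to_dial = competing_risk_split(
        trans.p_die_predialysis, trans.p_progress, settings.competing_risk)
    p_die_dial = np.array(trans.p_die_dialysis)

    occ = np.zeros((horizon + 1, 2 + K))
    inflow = np.zeros((horizon + 1, K))
    occ[0, 0] = 1.0
    for t in range(1, horizon + 1):
        pre, dial = occ[t - 1, 0], occ[t - 1, 1:-1]
        dead = occ[t - 1, -1]
        new_dead = dead + pre * pre_to_dead + float(dial @ p_die_dial)
        arriving = pre * pre_to_dial * split
        occ[t, 0] = pre * (1.0 - pre_to_dead - pre_to_dial)
        occ[t, 1:-1] = dial * (1.0 - p_die_dial) + arriving
        occ[t, -1] = new_dead
        inflow[t] = arriving
    return CohortTrace(arm=arm, dialysis_arms=dial_arms, occupancy=occ,
                       dialysis_inflow=inflow, cycles=horizon)


@dataclass
class StrategyTrace:
    """All arm sub-cohorts of one strategy plus their entry weights."""

    strategy: Strategy
    arms: list[TreatmentArm]
    traces: list[CohortTrace]

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.fraction_of_cohort for a in self.arms])

    def aggregate(self) -> np.ndarray:
        """Cohort-level three-state occupancy (fractions of the full
        entering cohort), rows = cycle boundaries 0..H."""
        w = self.weights
        return sum(wi * tr.three_state for wi, tr in zip(w, self.traces))

    @property
    def predialysis(self) -> np.ndarray:
        return self.aggregate()[:, 0]

    @property
    def dialysis(self) -> np.ndarray:
        return self.aggregate()[:, 1]

    @property
    def dead(self) -> np.ndarray:
        return self.aggregate()[:, 2]


def run_strategy(params: ModelParameters, strategy: Strategy) -> StrategyTrace:
    """Run every predialysis arm of a strategy."""
    arms = build_arms(params, strategy, Stage.PREDIALYSIS)
    traces = [run_cohort(arm, params) for arm in arms]
    return StrategyTrace(strategy=strategy, arms=arms, traces=traces)


def trace_dataframe(st: StrategyTrace, cohort_size: float = 1.0):
    """Tidy per-(arm, cycle, state) export of raw and corrected occupancy."""
    import pandas as pd

    rows = []
    for arm, tr in zip(st.arms, st.traces):
        three = tr.three_state * arm.fraction_of_cohort * cohort_size
        corr = half_cycle_correct(three)
        for t in range(three.shape[0]):
            for j, state in enumerate(("predialysis", "dialysis", "dead")):
                rows.append({
                    "strategy": st.strategy.value, "arm": arm.subgroup.value,
                    "cycle": t, "state": state, "occupancy": three[t, j],
                    "corrected_occupancy": corr[t - 1, j] if t >= 1 else np.nan,
                })
    return pd.DataFrame(rows)
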