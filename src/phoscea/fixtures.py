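"""Synthetic test inputs: degenerate parameter sets with closed-form
expectations, randomized-but-valid parameter sets, and a patient-level
microsimulation that serves as a brute-force oracle for the cohort
engine.

The closed forms here are computed from geometric-series survival
identities, independently of the cohort engine, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import Strategy, build_arms
from .markov import (StrategyTrace, build_transitions, competing_risk_split,
                     run_cohort)
from .parameters import ModelParameters, Stage, default_parameters


@dataclass
class Fixture:
    """A parameter set plus expected outputs, each with a tolerance and a
    note recording how the expectation was derived."""

    name: str
    params: ModelParameters
    expected: dict[str, tuple[float, float, str]]


def closed_form_life_years(p_die: float, horizon: int) -> float:
    """Undiscounted life years for a single absorbing-death state with
    constant annual death probability, half-cycle corrected.

    Survival after t cycles is q^t with q = 1 - p; crediting the mean of
    adjacent boundaries gives sum_t (q^(t-1) + q^t)/2
    = (1 - p/2) * (1 - q^H) / p.
    """
    if p_die == 0:
        return float(horizon)
    q = 1.0 - p_die
    return (1.0 - p_die / 2.0) * (1.0 - q ** horizon) / p_die


def _flat_rr_tables() -> dict:
    flat = [[0.0, None, 1.0, 1.0, 1.0]]
    return {"rr_tables.predialysis": flat, "rr_tables.dialysis": flat,
            "rr_tables.dialysis_alt": flat}


def _with_flat_rr(params: ModelParameters, **extra) -> ModelParameters:
    from .parameters import parameters_from_dict, parameters_to_dict

    raw = parameters_to_dict(params)
    flat = [[0.0, None, 1.0, 1.0, 1.0]]
    raw["rr_tables"] = {"predialysis": flat, "dialysis": flat, "dialysis_alt": flat}
    p = parameters_from_dict(raw)
    return p.copy_with(**extra) if extra else p


DEGENERATE_CASES = ("no_death", "no_progression", "certain_death_in_dialysis",
                    "zero_discount", "rr_all_one")


def degenerate_fixture(case: str) -> Fixture:
    """A parameter set whose headline outputs have closed forms.

    All degenerate cases flatten the SP risk tables to 1 and switch
    discounting off, so the closed-form geometric identities apply
    exactly.
    """
    base = default_parameters()
    H = base.settings.horizon_years
    if case == "no_death":
        p = _with_flat_rr(base, **{
            "epi.mortality_predialysis_annual": 0.0,
            "epi.mortality_dialysis_annual": 0.0,
            "settings.discount_rate": 0.0})
        return Fixture(case, p, {
            "life_years_per_patient": (float(H), 1e-9,
                                       "nobody dies: every patient lives the full horizon"),
        })
    if case == "no_progression":
        p = _with_flat_rr(base, **{
            "epi.progression_annual.value": 0.0,
            "epi.progression_annual.ci_low": 0.0,
            "epi.progression_annual.ci_high": 0.0,
            "settings.discount_rate": 0.0})
        pd_ = p.epi.mortality_predialysis_annual
        return Fixture(case, p, {
            "life_years_per_patient": (closed_form_life_years(pd_, H), 1e-9,
                                       "single-state geometric survival, half-cycle corrected"),
            "dialysis_years_per_patient": (0.0, 1e-12, "no progression: dialysis never entered"),
        })
    if case == "certain_death_in_dialysis":
        # non-responder SP is pinned to target so every arm progresses at
        # the base rate and a single geometric closed form applies
        p = _with_flat_rr(base, **{
            "epi.mortality_dialysis_annual": 1.0,
            "epi.sp_nonresponder_predialysis": base.settings.sp_target,
            "epi.sp_nonresponder_dialysis": base.settings.sp_target,
            "settings.discount_rate": 0.0})
        # predialysis follows a geometric with exit p_exit = p_die + (1-p_die)p_prog
        # (death-first); each progressor spends exactly one boundary in
        # dialysis, credited one half-cycle on entry and one on exit.
        p_die = p.epi.mortality_predialysis_annual
        p_prog_s = p.epi.progression_annual.value
        d, g = competing_risk_split(p_die, p_prog_s, p.settings.competing_risk)
        stay = 1.0 - d - g
        # predialysis years: sum_t (stay^(t-1)+stay^t)/2
        pre_years = closed_form_life_years(1.0 - stay, H)
        # progressors during cycle t: stay^(t-1) * g, each contributing one
        # full year of dialysis occupancy (half on arrival boundary t, half
        # at t+1) as long as t < H; the cycle-H cohort contributes half.
        t = np.arange(1, H + 1)
        arrivals = stay ** (t - 1) * g
        dial_years = float(arrivals[:-1].sum() + 0.5 * arrivals[-1])
        return Fixture(case, p, {
            "life_years_per_patient": (pre_years + dial_years, 1e-9,
                                       "geometric predialysis survival plus one dialysis year "
                                       "per progressor (certain death after one cycle)"),
            "dialysis_years_per_patient": (dial_years, 1e-9,
                                           "one occupancy-year per progressor, half-cycle credited"),
        })
    if case == "zero_discount":
        p = base.copy_with(**{"settings.discount_rate": 0.0})
        return Fixture(case, p, {
            "discount_factor_sum": (float(H), 1e-12,
                                    "at 0% every cycle's discount factor is 1"),
        })
    if case == "rr_all_one":
        p = _with_flat_rr(base)
        return Fixture(case, p, {
            "p_die_predialysis": (p.epi.mortality_predialysis_annual, 1e-12,
                                  "flat RR tables leave base rates untouched"),
            "p_progress_at_target": (p.epi.progression_annual.value, 1e-12,
                                     "responders at target progress at the base rate"),
        })
    raise ValueError(f"unknown degenerate case '{case}'; known: {DEGENERATE_CASES}")


def random_fixture(seed: int) -> Fixture:
    """A randomized, internally consistent parameter set.

    Rates are drawn within their printed 95% CI ranges, utilities in
    [0.3, 0.95]; the result always passes full parameter validation.
    """
    rng = np.random.default_rng(seed)
    base = default_parameters()

    def within(r):
        return float(rng.uniform(r.ci_low, r.ci_high))

    eff = base.efficacy
    u_pre = float(rng.uniform(0.35, 0.95))
    u_dial = float(rng.uniform(0.3, u_pre))
    overrides = {
        "efficacy.response_rate_cb_predialysis.value": within(eff.response_rate_cb_predialysis),
        "efficacy.response_rate_lc_predialysis.value": within(eff.response_rate_lc_predialysis),
        "efficacy.response_rate_cb_dialysis.value": within(eff.response_rate_cb_dialysis),
        "efficacy.response_rate_lc_dialysis.value": within(eff.response_rate_lc_dialysis),
        "epi.progression_annual.value": within(base.epi.progression_annual),
        "epi.rr_progression_per_mgdl.value": within(base.epi.rr_progression_per_mgdl),
        "epi.mortality_predialysis_annual": float(rng.uniform(0.05, 0.3)),
        "epi.mortality_dialysis_annual": float(rng.uniform(0.02, 0.3)),
        "utilities.utility_predialysis": u_pre,
        "utilities.utility_dialysis": u_dial,
        "settings.discount_rate": float(rng.uniform(0.0, 0.06)),
        "settings.horizon_years": int(rng.integers(5, 41)),
    }
    return Fixture(f"random-{seed}", base.copy_with(**overrides),
                   expected={"validation": (1.0, 0.0, "constructed to satisfy all invariants")})


@dataclass
class MicrosimResult:
    """Per-cycle three-state counts from the patient-level simulation."""

    counts: np.ndarray        # (H+1, 3): predialysis, dialysis, dead
    n_patients: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_patients

    def standard_errors(self) -> np.ndarray:
        """Binomial Monte-Carlo SE of each state fraction, per cycle."""
        f = self.fractions
        return np.sqrt(np.maximum(f * (1.0 - f), 0.0) / self.n_patients)


def microsim_oracle(params: ModelParameters, strategy: Strategy,
                    n_patients: int, seed: int) -> MicrosimResult:
    """Brute-force oracle: simulate individual annual state paths with the
    same transition probabilities and decision-tree splits as the cohort
    engine, and count state occupancy per cycle.

    Patients are assigned a predialysis arm by the decision-tree
    fractions, then walk the three-state chain; progression re-assigns a
    dialysis arm by the strategy's dialysis entry split.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    settings = params.settings
    H = settings.horizon_years

    pre_arms = build_arms(params, strategy, Stage.PREDIALYSIS)
    pre_fracs = np.array([a.fraction_of_cohort for a in pre_arms])
    dial_arms = build_arms(params, strategy, Stage.DIALYSIS)
    dial_fracs = np.array([a.fraction_of_cohort for a in dial_arms])

    exit_probs = []
    dial_die = None
    for arm in pre_arms:
        tr = build_transitions(arm, params)
        exit_probs.append(competing_risk_split(
            tr.p_die_predialysis, tr.p_progress, settings.competing_risk))
        dial_die = np.array(tr.p_die_dialysis)

    arm_idx = rng.choice(len(pre_arms), size=n_patients, p=pre_fracs / pre_fracs.sum())
    # state coding: 0 = predialysis, 1..K = dialysis arm, K+1 = dead
    K = len(dial_arms)
    DEAD = K + 1
    state = np.zeros(n_patients, dtype=np.int64)
    counts = np.zeros((H + 1, 3), dtype=np.int64)
    counts[0] = (n_patients, 0, 0)

    p_dead_by_arm = np.array([e[0] for e in exit_probs])
    p_prog_by_arm = np.array([e[1] for e in exit_probs])
    for t in range(1, H + 1):
        u = rng.random(n_patients)
        pre_mask = state == 0
        p_dead = p_dead_by_arm[arm_idx]
        p_prog = p_prog_by_arm[arm_idx]
        dies = pre_mask & (u < p_dead)
        progresses = pre_mask & ~dies & (u < p_dead + p_prog)
        state[dies] = DEAD
        n_prog = int(progresses.sum())
        if n_prog:
            state[progresses] = 1 + rng.choice(K, size=n_prog,
                                               p=dial_fracs / dial_fracs.sum())
        dial_mask = (state >= 1) & (state <= K) & ~progresses
        if dial_mask.any():
            d_u = rng.random(n_patients)
            d_dies = dial_mask & (d_u < dial_die[np.clip(state - 1, 0, K - 1)])
            state[d_dies] = DEAD
        counts[t] = ((state == 0).sum(),
                     ((state >= 1) & (state <= K)).sum(),
                     (state == DEAD).sum())
    return MicrosimResult(counts=counts, n_patients=n_patients)


def oracle_max_deviation(ms: MicrosimResult, cohort_fractions: np.ndarray) -> float:
    """Largest |microsim - cohort| deviation in units of the Monte-Carlo
    standard error implied by the cohort fractions (binomial under the
    null that the engine's occupancy is the simulation's law).

    The SE is floored at one patient so that near-empty cells (expected
    counts well below one, where the normal approximation to the
    binomial fails) register a one-patient discrepancy as ~1 SE rather
    than as a spurious many-sigma deviation.
    """
    f = ms.fractions
    c = np.asarray(cohort_fractions, dtype=float)
    n = ms.n_patients
    se_counts = np.maximum(np.sqrt(np.clip(c * (1.0 - c), 0.0, None) * n), 1.0)
    dev = np.abs(f - c) * n / se_counts
    return float(dev.max())


def cohort_three_state(params: ModelParameters, strategy: Strategy) -> np.ndarray:
    """Strategy-level three-state occupancy fractions from the cohort
    engine, for comparison against :func:`microsim_oracle`."""
    arms = build_arms(params, strategy, Stage.PREDIALYSIS)
    traces = [run_cohort(a, params) for a in arms]
    return StrategyTrace(strategy=strategy, arms=arms, traces=traces).aggregate()
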