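"""Initial decision tree: split the cohort by first-line calcium-binder
response and, under the second-line strategy, by lanthanum-carbonate
response among the non-responders.

Cohort arithmetic is expected-value (fractional patients), so the
subgroup sizes reported for a 1,000-patient cohort are products of the
printed response rates (e.g. 1000 x 0.445 = 445 first-line responders).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .parameters import ModelParameters, Stage


class Strategy(str, enum.Enum):
    CB_CONTINUED = "CB_continued"
    LC_SECOND_LINE = "LC_second_line"


class Subgroup(str, enum.Enum):
    """Response-status subgroup; determines regimen and representative SP."""

    CB_RESPONDER = "cb_responder"
    LC_RESPONDER = "lc_responder"
    NONRESPONDER_ON_CB = "nonresponder_on_cb"
    LC_FAILURE_SWITCHED_BACK = "lc_failure_switched_back"


#: subgroups whose maintenance regimen is lanthanum carbonate
LC_SUBGROUPS = frozenset({Subgroup.LC_RESPONDER})
#: subgroups that trial LC for `lc_trial_weeks` before switching back to CB
LC_TRIAL_SUBGROUPS = frozenset({Subgroup.LC_FAILURE_SWITCHED_BACK})


def classify_first_line(cohort_size: float, response_rate: float) -> tuple[float, float]:
    """Split a cohort into first-line responders and non-responders.

    Fractional counts are retained; ``responders + non_responders``
    equals ``cohort_size`` exactly.
    """
    if not 0 <= response_rate <= 1:
        raise ValueError(f"response_rate must be in [0, 1], got {response_rate}")
    responders = cohort_size * response_rate
    return responders, cohort_size - responders


def assign_second_line(non_responders: float, lc_response_rate: float) -> tuple[float, float]:
    """Split first-line non-responders into LC responders and LC failures
    (who switch back to CB after the trial period)."""
    if not 0 <= lc_response_rate <= 1:
        raise ValueError(f"lc_response_rate must be in [0, 1], got {lc_response_rate}")
    lc_responders = non_responders * lc_response_rate
    return lc_responders, non_responders - lc_responders


def lc_trial_year_cost_weight(lc_trial_weeks: float) -> tuple[float, float]:
    """Fractions of the first treatment year spent on LC vs CB by patients
    who trial LC and switch back."""
    if not 0 <= lc_trial_weeks <= 52:
        raise ValueError(f"lc_trial_weeks must be in [0, 52], got {lc_trial_weeks}")
    lc_fraction = lc_trial_weeks / 52.0
    return lc_fraction, 1.0 - lc_fraction


@dataclass(frozen=True)
class TreatmentArm:
    """One response-status subgroup within a strategy and stage.

    ``fraction_of_cohort`` is the share of the stage-entering population
    (the full cohort for predialysis arms; the share of dialysis entrants
    for dialysis arms).
    """

    strategy: Strategy
    stage: Stage
    subgroup: Subgroup
    fraction_of_cohort: float
    sp: float                       # representative serum phosphorus, mg/dL
    on_lc: bool                     # maintenance regimen is LC
    lc_trial: bool = False          # trials LC for lc_trial_weeks, then CB


def build_arms(params: ModelParameters, strategy: Strategy,
               stage: Stage = Stage.PREDIALYSIS) -> list[TreatmentArm]:
    """Response-status arms for a stage-entering population.

    Under continued CB the population splits into first-line responders
    and non-responders; under second-line LC the non-responders split
    again by LC response. Response is (re-)evaluated on entry to each
    stage when ``settings.re_evaluate_on_dialysis`` is set; otherwise the
    dialysis split simply carries the predialysis subgroup structure over
    (with dialysis-stage representative SP for non-responders).
    """
    eff, epi = params.efficacy, params.epi
    cb_rate = eff.response_rate("cb", stage)
    lc_rate = eff.response_rate("lc", stage)
    sp_resp = epi.sp_for(True, stage)
    sp_nonresp = epi.sp_for(False, stage)

    if stage == Stage.DIALYSIS and not params.settings.re_evaluate_on_dialysis:
        # carry predialysis structure over, only re-pricing SP for stage
        pre = build_arms(params, strategy, Stage.PREDIALYSIS)
        arms = []
        for arm in pre:
            responder = arm.subgroup in (Subgroup.CB_RESPONDER, Subgroup.LC_RESPONDER)
            arms.append(TreatmentArm(
                strategy=strategy, stage=Stage.DIALYSIS, subgroup=arm.subgroup,
                fraction_of_cohort=arm.fraction_of_cohort,
                sp=sp_resp if responder else sp_nonresp,
                on_lc=arm.on_lc, lc_trial=False))
        return arms

    responders, non_responders = classify_first_line(1.0, cb_rate)
    arms = [TreatmentArm(strategy=strategy, stage=stage, subgroup=Subgroup.CB_RESPONDER,
                         fraction_of_cohort=responders, sp=sp_resp, on_lc=False)]
    if strategy == Strategy.CB_CONTINUED:
        arms.append(TreatmentArm(
            strategy=strategy, stage=stage, subgroup=Subgroup.NONRESPONDER_ON_CB,
            fraction_of_cohort=non_responders, sp=sp_nonresp, on_lc=False))
    else:
        lc_responders, lc_failures = assign_second_line(non_responders, lc_rate)
        arms.append(TreatmentArm(
            strategy=strategy, stage=stage, subgroup=Subgroup.LC_RESPONDER,
            fraction_of_cohort=lc_responders, sp=sp_resp, on_lc=True))
        arms.append(TreatmentArm(
            strategy=strategy, stage=stage, subgroup=Subgroup.LC_FAILURE_SWITCHED_BACK,
            fraction_of_cohort=lc_failures, sp=sp_nonresp, on_lc=False, lc_trial=True))
    return arms


def responder_counts(params: ModelParameters, strategy: Strategy,
                     stage: Stage = Stage.PREDIALYSIS) -> float:
    """Expected number of responders (on any binder) in the entering
    cohort, scaled to ``settings.cohort_size``."""
    arms = build_arms(params, strategy, stage)
    frac = sum(a.fraction_of_cohort for a in arms
               if a.subgroup in (Subgroup.CB_RESPONDER, Subgroup.LC_RESPONDER))
    return frac * params.settings.cohort_size
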