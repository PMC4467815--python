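"""Model inputs: drug costing, serum-phosphorus risk strata, efficacy,
epidemiology, utilities and run settings.

All monetary amounts are euros (2013 value). Serum phosphorus (SP) is in
mg/dL. Annual probabilities are plain fractions in [0, 1]. Values are kept
unrounded internally; rounding happens only in the reporting layer.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator


class Stage(str, enum.Enum):
    """Disease stage tracked by the cohort model."""

    PREDIALYSIS = "predialysis"
    DIALYSIS = "dialysis"


class CBComposition(str, enum.Enum):
    """Which calcium-based binder(s) make up the comparator regimen."""

    AVERAGE = "average"
    CC_ONLY = "cc_only"
    CA_ONLY = "ca_only"


class FutureDialysisCostMode(str, enum.Enum):
    """How dialysis care in added life years is costed.

    ``attributable_only`` charges the €/year dialysis cost only on a
    strategy's per-cycle dialysis occupancy in excess of its comparator's
    (unrelated future dialysis costs excluded); ``full`` charges every
    dialysis patient-year in both strategies.
    """

    ATTRIBUTABLE_ONLY = "attributable_only"
    FULL = "full"


class RRApplication(str, enum.Enum):
    """How a relative risk scales an annual probability.

    ``rate_domain`` treats the RR as a hazard ratio: p' = 1 - (1-p)^RR.
    ``multiplicative`` uses p' = min(1, p * RR).
    """

    RATE_DOMAIN = "rate_domain"
    MULTIPLICATIVE = "multiplicative"


class CompetingRisk(str, enum.Enum):
    """Ordering of death vs progression within a predialysis cycle."""

    DEATH_FIRST = "death_first"
    INDEPENDENT_RENORMALIZED = "independent_renormalized"


class DiscountTiming(str, enum.Enum):
    """Exponent convention for discounting cycle t: t - 0.5 or t."""

    HALF_CYCLE = "half_cycle"
    END_CYCLE = "end_cycle"


# --------------------------------------------------------------------------
# Elementary cost arithmetic
# --------------------------------------------------------------------------

def apply_rebate(ex_factory_price: float, rebate_fraction: float) -> float:
    """Apply the mandatory rebate to an ex-factory pack price.

    Parameters
    ----------
    ex_factory_price : list price in €, must be >= 0.
    rebate_fraction : fraction withheld, in [0, 1).
    """
    if ex_factory_price < 0:
        raise ValueError(f"ex_factory_price must be >= 0, got {ex_factory_price}")
    if not 0 <= rebate_fraction < 1:
        raise ValueError(f"rebate_fraction must be in [0, 1), got {rebate_fraction}")
    return ex_factory_price * (1.0 - rebate_fraction)


def cost_per_gram(pack_price: float, tablets_per_pack: int, mg_per_tablet: float) -> float:
    """€ per gram of active substance implied by a pack.

    The unrounded value is used in all downstream arithmetic; two-decimal
    display is left to the reporting layer.
    """
    grams = tablets_per_pack * mg_per_tablet / 1000.0
    if grams <= 0:
        raise ValueError("pack must contain a positive mass of active substance")
    return pack_price / grams


def annual_drug_cost(daily_dose_mg: float, cost_per_g: float, days_per_year: float = 365) -> float:
    """€ per treatment-year at a given daily dose."""
    return daily_dose_mg / 1000.0 * days_per_year * cost_per_g


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class DrugSpec(BaseModel):
    """One binder: pack presentation, price (rebate already applied in the
    bundled inputs) and stage-specific daily doses.

    ``cost_per_gram_override`` exists because one catalogue row's printed
    €/g is not reproducible from its pack price; when set, it takes
    precedence over the pack-derived value.
    """

    name: str
    mg_per_tablet: float = Field(gt=0)
    tablets_per_pack: int = Field(gt=0)
    pack_price: float = Field(ge=0)
    daily_dose_predialysis: float = Field(ge=0)
    daily_dose_dialysis: float = Field(ge=0)
    cost_per_gram_override: Optional[float] = None

    @property
    def cost_per_g(self) -> float:
        if self.cost_per_gram_override is not None:
            return self.cost_per_gram_override
        return cost_per_gram(self.pack_price, self.tablets_per_pack, self.mg_per_tablet)

    def daily_dose(self, stage: Stage) -> float:
        return (self.daily_dose_predialysis if stage == Stage.PREDIALYSIS
                else self.daily_dose_dialysis)

    def annual_cost(self, stage: Stage, days_per_year: float = 365) -> float:
        return annual_drug_cost(self.daily_dose(stage), self.cost_per_g, days_per_year)


class RRStratum(BaseModel):
    """One SP band and its mortality relative risk with a 95% CI.

    Bands are lower-inclusive, upper-exclusive; the open end strata use
    0 and +inf.
    """

    sp_low: float = Field(ge=0)
    sp_high: float
    rr: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "RRStratum":
        if not self.sp_low < self.sp_high:
            raise ValueError(f"sp_low {self.sp_low} must be < sp_high {self.sp_high}")
        return self

    @property
    def ci_consistent(self) -> bool:
        """Whether the printed CI actually brackets the point estimate."""
        return self.ci_low <= self.rr <= self.ci_high

    def contains(self, sp: float) -> bool:
        return self.sp_low <= sp < self.sp_high


class RRTable(BaseModel):
    """A piecewise-constant SP -> mortality RR step function."""

    strata: list[RRStratum]

    @model_validator(mode="after")
    def _check(self) -> "RRTable":
        strata = sorted(self.strata, key=lambda s: s.sp_low)
        if not strata:
            raise ValueError("RR table must have at least one stratum")
        if strata[0].sp_low != 0:
            raise ValueError("RR table must start at SP 0")
        if not math.isinf(strata[-1].sp_high):
            raise ValueError("RR table must be open-ended above")
        for a, b in zip(strata, strata[1:]):
            if a.sp_high != b.sp_low:
                raise ValueError(
                    f"RR strata must tile (0, inf): gap/overlap at {a.sp_high} vs {b.sp_low}")
        object.__setattr__(self, "strata", strata)
        return self

    def stratum_for(self, sp: float) -> RRStratum:
        if sp <= 0:
            raise ValueError(f"SP must be positive, got {sp}")
        for s in self.strata:
            if s.contains(sp):
                return s
        raise ValueError(f"SP {sp} not covered by RR table")  # pragma: no cover


def rr_for_sp(table: RRTable, sp: float) -> float:
    """Mortality relative risk for a serum-phosphorus level.

    A boundary value belongs to the stratum whose lower bound equals it.
    """
    return table.stratum_for(sp).rr


class RateWithCI(BaseModel):
    """A probability or ratio with its printed 95% CI."""

    value: float
    ci_low: float
    ci_high: float

    @model_validator(mode="after")
    def _check(self) -> "RateWithCI":
        if not self.ci_low <= self.value <= self.ci_high:
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) must bracket value {self.value}")
        return self


class EfficacyParams(BaseModel):
    """Trial-derived response rates (fraction reaching the SP target) and
    the trial arm sizes used for binomial resampling in the PSA."""

    response_rate_cb_predialysis: RateWithCI
    response_rate_cb_dialysis: RateWithCI
    response_rate_lc_predialysis: RateWithCI
    response_rate_lc_dialysis: RateWithCI
    n_trial_cb_pre: int = Field(gt=0)
    n_trial_lc_pre: int = Field(gt=0)
    n_trial_cb_dial: int = Field(gt=0)
    n_trial_lc_dial: int = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "EfficacyParams":
        for field in ("response_rate_cb_predialysis", "response_rate_cb_dialysis",
                      "response_rate_lc_predialysis", "response_rate_lc_dialysis"):
            r = getattr(self, field)
            if not 0 <= r.value <= 1:
                raise ValueError(f"{field} must be in [0, 1], got {r.value}")
        return self

    def response_rate(self, drug: str, stage: Stage) -> float:
        key = f"response_rate_{drug}_{'predialysis' if stage == Stage.PREDIALYSIS else 'dialysis'}"
        return getattr(self, key).value


class EpidemiologyParams(BaseModel):
    """Baseline annual mortality and progression, the per-mg/dL progression
    relative risk, and representative SP levels per response status.

    ``mortality_dialysis_annual`` has no published point value for this
    population and must be supplied (the bundled inputs carry a documented
    calibrated value).
    """

    mortality_predialysis_annual: float = Field(ge=0, le=1)
    mortality_dialysis_annual: float = Field(ge=0, le=1)
    mortality_dialysis_sd: float = Field(default=0.0, ge=0)
    progression_annual: RateWithCI
    rr_progression_per_mgdl: RateWithCI
    sp_responder: float = Field(gt=0)
    sp_nonresponder_predialysis: float = Field(gt=0)
    sp_nonresponder_dialysis: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "EpidemiologyParams":
        if not 0 <= self.progression_annual.value <= 1:
            raise ValueError("progression_annual must be in [0, 1]")
        if self.rr_progression_per_mgdl.value <= 0:
            raise ValueError("rr_progression_per_mgdl must be > 0")
        return self

    def sp_for(self, responder: bool, stage: Stage) -> float:
        if responder:
            return self.sp_responder
        return (self.sp_nonresponder_predialysis if stage == Stage.PREDIALYSIS
                else self.sp_nonresponder_dialysis)


class UtilityParams(BaseModel):
    """Stage utilities and the vomiting disutility attached to LC use."""

    utility_predialysis: float
    utility_dialysis: float
    vomit_decrement: float = Field(ge=0)
    vomit_rate_lc_predialysis: float = Field(ge=0, le=1)
    vomit_rate_lc_dialysis: float = Field(ge=0, le=1)
    utility_sd: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "UtilityParams":
        for field in ("utility_predialysis", "utility_dialysis"):
            u = getattr(self, field)
            if not 0 <= u <= 1:
                raise ValueError(f"{field} must be in [0, 1], got {u}")
        return self

    def utility(self, stage: Stage) -> float:
        return (self.utility_predialysis if stage == Stage.PREDIALYSIS
                else self.utility_dialysis)

    def vomit_rate(self, stage: Stage) -> float:
        return (self.vomit_rate_lc_predialysis if stage == Stage.PREDIALYSIS
                else self.vomit_rate_lc_dialysis)


class RunSettings(BaseModel):
    """Cohort, horizon, discounting, thresholds and modelling conventions."""

    model_config = {"validate_assignment": True}

    cohort_size: float = Field(ge=1)
    horizon_years: int = Field(ge=1, le=40)
    discount_rate: float = Field(ge=0)
    days_per_year: float = Field(default=365, gt=0)
    threshold_lambda: float = Field(default=30_000, ge=0)
    sp_target: float = Field(gt=0)
    sp_target_dialysis: Optional[float] = None
    sp_initiation_predialysis: float = Field(gt=0)
    sp_initiation_dialysis: float = Field(gt=0)
    future_dialysis_cost_mode: FutureDialysisCostMode = FutureDialysisCostMode.ATTRIBUTABLE_ONLY
    dialysis_annual_cost: float = Field(ge=0)
    rebate_fraction: float = Field(ge=0, lt=1)
    rebate_applied: bool = True
    lc_trial_weeks: float = Field(ge=0, le=52)
    seed: int = 12345
    rr_application: RRApplication = RRApplication.RATE_DOMAIN
    competing_risk: CompetingRisk = CompetingRisk.DEATH_FIRST
    discount_timing: DiscountTiming = DiscountTiming.HALF_CYCLE
    re_evaluate_on_dialysis: bool = True
    cost_cv: float = Field(default=0.2, ge=0)

    def sp_target_for(self, stage: Stage) -> float:
        if stage == Stage.DIALYSIS and self.sp_target_dialysis is not None:
            return self.sp_target_dialysis
        return self.sp_target


class ModelParameters(BaseModel):
    """The complete validated input set for one model run."""

    model_config = {"validate_assignment": True}

    drugs: dict[str, DrugSpec]
    efficacy: EfficacyParams
    epi: EpidemiologyParams
    rr_predialysis: RRTable
    rr_dialysis: RRTable
    rr_dialysis_alt: RRTable
    utilities: UtilityParams
    settings: RunSettings
    cb_composition: CBComposition = CBComposition.AVERAGE
    use_alt_dialysis_rr: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        for key in ("lc", "cc", "ca"):
            if key not in self.drugs:
                raise ValueError(f"drugs must include '{key}'")
        return self

    # -- derived lookups ---------------------------------------------------

    def rr_table(self, stage: Stage) -> RRTable:
        if stage == Stage.PREDIALYSIS:
            return self.rr_predialysis
        return self.rr_dialysis_alt if self.use_alt_dialysis_rr else self.rr_dialysis

    def mortality_rr(self, stage: Stage, sp: float) -> float:
        return rr_for_sp(self.rr_table(stage), sp)

    def lc_annual_cost(self, stage: Stage) -> float:
        return self.drugs["lc"].annual_cost(stage, self.settings.days_per_year)

    def cb_annual_cost(self, stage: Stage) -> float:
        """Annual comparator cost: the CC/CA mean by default, or a single
        binder under the cc_only / ca_only compositions."""
        days = self.settings.days_per_year
        if self.cb_composition == CBComposition.CC_ONLY:
            return self.drugs["cc"].annual_cost(stage, days)
        if self.cb_composition == CBComposition.CA_ONLY:
            return self.drugs["ca"].annual_cost(stage, days)
        return 0.5 * (self.drugs["cc"].annual_cost(stage, days)
                      + self.drugs["ca"].annual_cost(stage, days))

    def copy_with(self, **overrides) -> "ModelParameters":
        """Deep copy with dotted-path overrides, e.g.
        ``copy_with(**{"settings.discount_rate": 0.06})``."""
        p = self.model_copy(deep=True)
        for path, value in overrides.items():
            obj = p
            parts = path.split(".")
            for part in parts[:-1]:
                obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
            leaf = parts[-1]
            if isinstance(obj, dict):
                if leaf not in obj:
                    raise KeyError(f"unknown parameter override '{path}'")
                obj[leaf] = value
            else:
                if not hasattr(obj, leaf):
                    raise KeyError(f"unknown parameter override '{path}'")
                setattr(obj, leaf, value)
        return ModelParameters.model_validate(p.model_dump())


# --------------------------------------------------------------------------
# Loading / saving
# --------------------------------------------------------------------------

_REQUIRED_EPI_FIELDS = ("mortality_dialysis_annual",)


def _rr_table_from_rows(rows: Sequence[Sequence[float]]) -> RRTable:
    strata = []
    for lo, hi, rr, ci_lo, ci_hi in rows:
        strata.append(RRStratum(
            sp_low=lo, sp_high=math.inf if hi in (None, "inf") else hi,
            rr=rr, ci_low=ci_lo, ci_high=ci_hi))
    return RRTable(strata=strata)


def _rate(d) -> RateWithCI:
    if isinstance(d, dict):
        return RateWithCI(value=d["value"], ci_low=d["ci"][0], ci_high=d["ci"][1])
    return RateWithCI(value=d, ci_low=d, ci_high=d)


def parameters_from_dict(raw: dict) -> ModelParameters:
    """Build and validate a ModelParameters from a parsed config mapping."""
    epi_raw = raw.get("epidemiology", {})
    for field in _REQUIRED_EPI_FIELDS:
        if field not in epi_raw:
            raise ValueError(
                f"missing required field 'epidemiology.{field}': this value is not "
                "published for the modelled population and must be supplied explicitly")
    drugs = {k: DrugSpec(**v) for k, v in raw["drugs"].items()}
    eff_raw = raw["efficacy"]
    efficacy = EfficacyParams(
        response_rate_cb_predialysis=_rate(eff_raw["response_rate_cb_predialysis"]),
        response_rate_cb_dialysis=_rate(eff_raw["response_rate_cb_dialysis"]),
        response_rate_lc_predialysis=_rate(eff_raw["response_rate_lc_predialysis"]),
        response_rate_lc_dialysis=_rate(eff_raw["response_rate_lc_dialysis"]),
        n_trial_cb_pre=eff_raw["n_trial_cb_pre"],
        n_trial_lc_pre=eff_raw["n_trial_lc_pre"],
        n_trial_cb_dial=eff_raw["n_trial_cb_dial"],
        n_trial_lc_dial=eff_raw["n_trial_lc_dial"],
    )
    epi = EpidemiologyParams(
        mortality_predialysis_annual=epi_raw["mortality_predialysis_annual"],
        mortality_dialysis_annual=epi_raw["mortality_dialysis_annual"],
        mortality_dialysis_sd=epi_raw.get("mortality_dialysis_sd", 0.0),
        progression_annual=_rate(epi_raw["progression_annual"]),
        rr_progression_per_mgdl=_rate(epi_raw["rr_progression_per_mgdl"]),
        sp_responder=epi_raw["sp_responder"],
        sp_nonresponder_predialysis=epi_raw["sp_nonresponder_predialysis"],
        sp_nonresponder_dialysis=epi_raw["sp_nonresponder_dialysis"],
    )
    utilities = UtilityParams(**raw["utilities"])
    settings = RunSettings(**raw["settings"])
    return ModelParameters(
        drugs=drugs,
        efficacy=efficacy,
        epi=epi,
        rr_predialysis=_rr_table_from_rows(raw["rr_tables"]["predialysis"]),
        rr_dialysis=_rr_table_from_rows(raw["rr_tables"]["dialysis"]),
        rr_dialysis_alt=_rr_table_from_rows(raw["rr_tables"]["dialysis_alt"]),
        utilities=utilities,
        settings=settings,
        cb_composition=CBComposition(raw.get("cb_composition", "average")),
        use_alt_dialysis_rr=raw.get("use_alt_dialysis_rr", False),
    )


def load_parameters(config_path: str | Path) -> ModelParameters:
    """Load and validate a YAML parameter file."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} did not parse to a mapping")
    return parameters_from_dict(raw)


def parameters_to_dict(params: ModelParameters) -> dict:
    """Serialize back to the config-file layout (round-trips with
    :func:`parameters_from_dict`)."""

    def rate_out(r: RateWithCI):
        return {"value": r.value, "ci": [r.ci_low, r.ci_high]}

    def rows_out(table: RRTable):
        return [[s.sp_low, None if math.isinf(s.sp_high) else s.sp_high,
                 s.rr, s.ci_low, s.ci_high] for s in table.strata]

    eff = params.efficacy
    epi = params.epi
    return {
        "drugs": {k: v.model_dump(exclude_none=True) for k, v in params.drugs.items()},
        "efficacy": {
            "response_rate_cb_predialysis": rate_out(eff.response_rate_cb_predialysis),
            "response_rate_cb_dialysis": rate_out(eff.response_rate_cb_dialysis),
            "response_rate_lc_predialysis": rate_out(eff.response_rate_lc_predialysis),
            "response_rate_lc_dialysis": rate_out(eff.response_rate_lc_dialysis),
            "n_trial_cb_pre": eff.n_trial_cb_pre,
            "n_trial_lc_pre": eff.n_trial_lc_pre,
            "n_trial_cb_dial": eff.n_trial_cb_dial,
            "n_trial_lc_dial": eff.n_trial_lc_dial,
        },
        "epidemiology": {
            "mortality_predialysis_annual": epi.mortality_predialysis_annual,
            "mortality_dialysis_annual": epi.mortality_dialysis_annual,
            "mortality_dialysis_sd": epi.mortality_dialysis_sd,
            "progression_annual": rate_out(epi.progression_annual),
            "rr_progression_per_mgdl": rate_out(epi.rr_progression_per_mgdl),
            "sp_responder": epi.sp_responder,
            "sp_nonresponder_predialysis": epi.sp_nonresponder_predialysis,
            "sp_nonresponder_dialysis": epi.sp_nonresponder_dialysis,
        },
        "rr_tables": {
            "predialysis": rows_out(params.rr_predialysis),
            "dialysis": rows_out(params.rr_dialysis),
            "dialysis_alt": rows_out(params.rr_dialysis_alt),
        },
        "utilities": params.utilities.model_dump(),
        "settings": params.settings.model_dump(mode="json"),
        "cb_composition": params.cb_composition.value,
        "use_alt_dialysis_rr": params.use_alt_dialysis_rr,
    }


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The bundled base-case parameter set."""
    ref = resources.files("phoscea.data") / "params_basecase.yaml"
    with resources.as_file(ref) as path:
        return load_parameters(path)
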