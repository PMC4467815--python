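"""One-way scenario analysis and probabilistic sensitivity analysis.

The ten one-way scenarios re-run the deterministic pipeline under a
single parameter override each. The PSA jointly resamples all uncertain
inputs with the distribution families conventional for each parameter
type — lognormal for costs, binomial (at trial size) for response
probabilities, normal for relative risks and dialysis mortality, beta
for utilities — and summarises the incremental cloud on the
cost-effectiveness plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import ComparisonResult, Dominance, evaluate
from .parameters import ModelParameters, RateWithCI, RRTable


# --------------------------------------------------------------------------
# One-way scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named one-way deviation from the base case."""

    id: str
    description: str
    overrides: dict


STANDARD_SCENARIOS: dict[str, Scenario] = {s.id: s for s in [
    Scenario("S1", "Time horizon 5 years", {"settings.horizon_years": 5}),
    Scenario("S2", "Time horizon 10 years", {"settings.horizon_years": 10}),
    Scenario("S3", "Unrelated future dialysis costs included",
             {"settings.future_dialysis_cost_mode": "full"}),
    Scenario("S4", "Dialysis SP target 5.0 mg/dL",
             {"settings.sp_target_dialysis": 5.0}),
    Scenario("S5", "Annual discount rate 6%", {"settings.discount_rate": 0.06}),
    Scenario("S6", "Annual discount rate 0%", {"settings.discount_rate": 0.0}),
    Scenario("S7", "Comparator calcium acetate only", {"cb_composition": "ca_only"}),
    Scenario("S8", "Comparator calcium carbonate only", {"cb_composition": "cc_only"}),
    Scenario("S9", "Alternative dialysis mortality-risk set",
             {"use_alt_dialysis_rr": True}),
    Scenario("S10", "No utility decrement for vomiting",
             {"utilities.vomit_decrement": 0.0}),
]}


def run_scenario(scenario: Scenario, base: ModelParameters) -> ComparisonResult:
    """Apply a scenario's overrides to a copy of the base parameters and
    re-run the full pipeline. Unknown override paths raise ``KeyError``."""
    params = base.copy_with(**scenario.overrides)
    return evaluate(params)


def run_scenarios(base: ModelParameters,
                  ids: list[str] | None = None) -> dict[str, ComparisonResult]:
    """Run the requested (default: all ten) one-way scenarios."""
    ids = list(STANDARD_SCENARIOS) if not ids else ids
    out: dict[str, ComparisonResult] = {}
    for sid in ids:
        if sid not in STANDARD_SCENARIOS:
            raise KeyError(f"unknown scenario id '{sid}'; known: {list(STANDARD_SCENARIOS)}")
        out[sid] = run_scenario(STANDARD_SCENARIOS[sid], base)
    return out


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASpec:
    """PSA settings.

    ``variance_scale`` multiplies every sampling dispersion (binomial
    trial sizes are divided by its square); 0 collapses all
    distributions to their point estimates.
    """

    n_iterations: int = 1000
    seed: int = 12345
    variance_scale: float = 1.0
    lambda_grid: tuple[float, ...] = (0, 10_000, 20_000, 30_000, 40_000,
                                      45_000, 50_000, 60_000, 80_000, 100_000)

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.variance_scale < 0:
            raise ValueError("variance_scale must be >= 0")


@dataclass
class PSAResult:
    """The incremental cloud and its acceptability summaries."""

    points: pd.DataFrame            # iteration, delta_cost, delta_qalys, dominant
    fraction_dominant: float
    ceac: dict[float, float]        # lambda -> fraction cost-effective (NMB > 0)
    n_iterations: int
    seed: int

    def ceac_at(self, lam: float) -> float:
        return self.ceac[lam]


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw moment-matched to (mean, cv); degenerate at cv=0."""
    if mean <= 0 or cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _normal_pos(rng: np.random.Generator, mean: float, sd: float,
                upper: float | None = None) -> float:
    """Normal draw truncated below at ~0 (and optionally above)."""
    if sd == 0:
        return mean
    x = float(rng.normal(mean, sd))
    x = max(x, 1e-9)
    if upper is not None:
        x = min(x, upper)
    return x


def _beta_mm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw by method of moments; falls back to the mean when the
    requested variance is infeasible for the support."""
    if sd == 0 or mean <= 0 or mean >= 1:
        return mean
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError(
            f"beta moment match infeasible: sd {sd} too large for mean {mean}")
    k = mean * (1 - mean) / var - 1
    return float(rng.beta(mean * k, (1 - mean) * k))


def _rr_sd(stratum) -> float:
    """Normal sd for an RR stratum: CI half-width / 1.96, falling back to
    10% of the point estimate when the printed CI is inconsistent."""
    if stratum.ci_consistent and stratum.ci_high > stratum.ci_low:
        return (stratum.ci_high - stratum.ci_low) / 3.92
    if stratum.ci_high == stratum.ci_low == stratum.rr:
        return 0.0
    return 0.1 * stratum.rr


def _sample_rr_table(rng: np.random.Generator, table: RRTable, scale: float) -> None:
    for s in table.strata:
        sd = _rr_sd(s) * scale
        if sd > 0:
            s.ci_low, s.ci_high = 1e-9, np.inf
            s.rr = _normal_pos(rng, s.rr, sd)


def _binomial_rate(rng: np.random.Generator, rate: float, n: int, scale: float) -> float:
    if scale == 0:
        return rate
    n_eff = max(1, int(round(n / (scale * scale))))
    return float(rng.binomial(n_eff, rate)) / n_eff


def sample_parameters(base: ModelParameters, spec: PSASpec,
                      rng: np.random.Generator) -> ModelParameters:
    """One joint draw of the uncertain parameters.

    Costs (pack prices / €-per-gram overrides and the annual dialysis
    cost) are lognormal with the configured coefficient of variation;
    response rates are binomial at their trial sizes; mortality relative
    risks (every stratum) and the progression RR are normal with sd from
    the printed 95% CI (CI half-width / 1.96, 10%-of-mean fallback for
    inconsistent CIs); dialysis baseline mortality is normal; stage
    utilities are beta by method of moments. Everything else is fixed.
    """
    p = base.model_copy(deep=True)
    scale = spec.variance_scale
    cv = base.settings.cost_cv * scale

    # costs
    for drug in p.drugs.values():
        if drug.cost_per_gram_override is not None:
            drug.cost_per_gram_override = _lognormal(rng, drug.cost_per_gram_override, cv)
        else:
            drug.pack_price = _lognormal(rng, drug.pack_price, cv)
    p.settings.dialysis_annual_cost = _lognormal(rng, p.settings.dialysis_annual_cost, cv)

    # response rates (binomial at trial size)
    eff = p.efficacy
    pairs = [("response_rate_cb_predialysis", eff.n_trial_cb_pre),
             ("response_rate_lc_predialysis", eff.n_trial_lc_pre),
             ("response_rate_cb_dialysis", eff.n_trial_cb_dial),
             ("response_rate_lc_dialysis", eff.n_trial_lc_dial)]
    for name, n in pairs:
        r: RateWithCI = getattr(eff, name)
        r.ci_low, r.ci_high = 0.0, 1.0
        r.value = _binomial_rate(rng, r.value, n, scale)

    # relative risks
    _sample_rr_table(rng, p.rr_predialysis, scale)
    _sample_rr_table(rng, p.rr_dialysis, scale)
    prr = p.epi.rr_progression_per_mgdl
    sd = (prr.ci_high - prr.ci_low) / 3.92 * scale
    prr.ci_low, prr.ci_high = 0.0, np.inf
    prr.value = _normal_pos(rng, prr.value, sd)

    # dialysis mortality (normal, truncated to [0, 1])
    p.epi.mortality_dialysis_annual = _normal_pos(
        rng, p.epi.mortality_dialysis_annual, p.epi.mortality_dialysis_sd * scale,
        upper=1.0)

    # utilities (beta)
    u = p.utilities
    u.utility_predialysis = _beta_mm(rng, u.utility_predialysis, u.utility_sd * scale)
    u.utility_dialysis = _beta_mm(rng, u.utility_dialysis, u.utility_sd * scale)
    return p


def run_psa(base: ModelParameters, spec: PSASpec) -> PSAResult:
    """Monte-Carlo PSA: ``n_iterations`` full-model evaluations under
    jointly resampled parameters.

    ``fraction_dominant`` is the share of iterations with negative
    incremental cost and positive incremental QALYs; the CEAC reports,
    per willingness-to-pay threshold, the share with positive net
    monetary benefit.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for it in range(spec.n_iterations):
        params = sample_parameters(base, spec, rng)
        res = evaluate(params)
        rows.append({
            "iteration": it,
            "delta_cost": res.ce.delta_cost,
            "delta_qalys": res.ce.delta_qalys,
            "dominant": res.ce.dominance == Dominance.DOMINANT,
        })
    points = pd.DataFrame(rows)
    dc = points["delta_cost"].to_numpy()
    dq = points["delta_qalys"].to_numpy()
    ceac = {float(lam): float(np.mean(lam * dq - dc > 0)) for lam in spec.lambda_grid}
    return PSAResult(points=points,
                     fraction_dominant=float(points["dominant"].mean()),
                     ceac=ceac, n_iterations=spec.n_iterations, seed=spec.seed)
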