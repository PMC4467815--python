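# Methods

## Model structure

Two strategies for hyperphosphatemia in CKD are compared over a lifetime
(40-year) horizon for a cohort entering in predialysis: continued
calcium-based binders (CB) for everyone, versus second-line lanthanum
carbonate (LC) for CB non-responders. A decision tree assigns response
status (expected-value arithmetic: a 1,000-patient cohort with a 44.5%
CB response rate contributes 445 responders, fractional cohorts are kept
unrounded internally), and each response subgroup runs through a
three-state annual-cycle Markov cohort model — predialysis, dialysis,
death — with death absorbing and no dialysis→predialysis transition.

Response is evaluated at model entry and re-evaluated once on arrival in
dialysis with the dialysis-stage response rates (switchable:
`settings.re_evaluate_on_dialysis`). Patients who trial LC without
reaching target spend 8 of 52 weeks of that stage-entry year on LC
(`settings.lc_trial_weeks`) and are charged the LC–CB cost difference
for that fraction, once per stage.

## Risks and serum phosphorus

No serum-phosphorus (SP) trajectory is modelled. Each subgroup carries a
representative SP: responders 4.0 mg/dL (at target; `epi.sp_responder`),
non-responders the trial baseline means — 5.7 mg/dL in predialysis and
6.0 mg/dL in dialysis (the dialysis trials randomized patients above
5.58 mg/dL). SP enters twice:

* **Mortality.** Annual baseline mortality (12.3%/yr predialysis; see
  *Calibration* for dialysis) is adjusted by the SP-stratum relative
  risk. Strata are lower-inclusive/upper-exclusive. The default
  adjustment is in the rate domain, `p = 1 − (1 − p₀)^RR`, because the
  largest printed RRs (up to 2.02) would otherwise push annual
  probabilities above plausible hazards; a plain multiplicative variant
  is available (`settings.rr_application`).
* **Progression.** Annual progression 14.3%/yr at target, scaled by
  `1.19^(SP − 4.6)` per mg/dL of excess SP, applied in the same domain.
  The source prints the progression RR "per 1 g/dL"; since SP is
  reported in mg/dL throughout, this is read as per 1 mg/dL.

Competing risks within a predialysis cycle default to death-first
(progression applies to survivors), which conserves occupancy without
renormalization; an independent-renormalized variant is switchable
(`settings.competing_risk`).

## Economics

Occupancy is half-cycle corrected (mean of adjacent cycle boundaries)
and all streams are discounted at 3%/yr with exponent t − 0.5, matching
mid-cycle accrual (end-of-cycle exponent available,
`settings.discount_timing`; the difference is ~1.5% of totals). Costs:
drug acquisition per corrected occupancy-year at catalogue annual costs,
and dialysis at €42,555.6 per patient-year. QALYs: 0.71 per predialysis
year, 0.61 per dialysis year, minus 0.04082 per vomiting episode at
4.0%/yr (predialysis) or 7.2%/yr (dialysis) for patients maintained on
LC.

**Unrelated future dialysis costs.** In the base case, dialysis care in
a strategy's added life years is excluded: per cycle, a strategy is
charged only `max(0, own_dialysis − comparator_dialysis_share_among_
survivors × own_alive)` — dialysis use in excess of what the comparator
policy would produce at matched survival. This operationalizes the
exclusion asymmetry of the source analysis (the comparator is charged
for dialysis caused by earlier progression; the intervention is not
charged for dialysis accrued merely because its patients live longer).
A naive symmetric per-cycle floor was rejected: the LC strategy's
survival gains re-fill its dialysis state, so the symmetric rule charges
the intervention for added-survival dialysis — exactly the cost the
base case is meant to exclude. Scenario S3 charges every dialysis
occupancy-year in both strategies instead.

Incremental results report ΔC, ΔE, dominance (quadrant of the CE
plane), ICERs per QALY and per life year (numbers only in trade-off
quadrants), and NMB = λ·ΔQALY − ΔC at λ = €30,000/QALY.

## Drug costing

Annual drug costs reproduce the 2013 catalogue: LC €1,702/€2,042
(predialysis/dialysis), CC €30/€50, CA €68/€136, CB average €49/€93, at
365 days/year, from rebate-inclusive pack prices (7.5% mandatory
deduction already applied in the bundled file; `apply_rebate` handles
raw ex-factory prices). Two catalogue inconsistencies are carried as
documented choices rather than silently resolved: the CA €/g (€0.124)
is not derivable from its pack price (€7.13/75 g = €0.095) and is kept
as an explicit override because the printed annual costs require it;
and the published dosage table (CC 3,000/1,500, CA 5,000/3,000 mg/day)
cannot yield the published annual costs, so the bundled doses are the
ones the annual costs imply (CC 3,000/5,000, CA 1,500/3,000 mg/day).
Annual costs, which drive results, are authoritative.

## Calibration

Baseline annual dialysis mortality has no published value for this
cohort. It is calibrated (one-dimensional root find,
`scripts/calibrate_dialysis_mortality.py`) so the continued-CB strategy
accrues the published 6.868 discounted life years per patient; the
result, 0.044051/yr, is recorded in the bundled parameter file. This is
far below registry dialysis mortality (~15%/yr): it is the value the
published life-years total *implies* given the printed predialysis
rates, not an epidemiological estimate, and it mainly stretches dialysis
survival (hence dialysis-related costs) rather than reshaping the
incremental comparison's sign.

## Sensitivity analysis

Ten one-way scenarios rerun the pipeline under single overrides:
horizons of 5 and 10 years, full future dialysis costs, a relaxed
dialysis SP target (5.0 mg/dL; implemented as the target change only —
no re-derived response rates exist, so its effect here is minimal and
the scenario is an acknowledged approximation), 6% and 0% discounting,
single-binder comparators, an alternative dialysis mortality-risk table,
and removal of the vomiting disutility.

The PSA jointly resamples, per iteration: costs (pack prices / €-per-
gram and the dialysis year cost) lognormally with coefficient of
variation 0.2 (no dispersion is published for costs; 0.2 is a
conventional default, `settings.cost_cv`); response rates binomially at
their trial arm sizes (28, 56, 123, 257); every mortality RR stratum and
the progression RR normally with sd = CI half-width / 1.96, falling back
to 10% of the mean where a printed CI does not bracket its point
estimate (the predialysis strata above 5.5 mg/dL); dialysis baseline
mortality normally with sd = 10% of the calibrated mean; stage utilities
from method-of-moments beta distributions with sd 0.05. Sampling is at
the rate level; all other inputs stay fixed. Summaries: the incremental
cloud, the fraction of dominant iterations, and a CEAC by the NMB > 0
criterion over a λ grid including €30,000 and €45,000. A
`variance_scale` dial shrinks every dispersion (binomial n grows as
1/scale²); at 0 the cloud collapses exactly to the deterministic result,
which the tests exercise.

## Validation

* **Closed forms.** Degenerate parameter sets (no death, no
  progression, certain dialysis death, flat risk tables, zero discount)
  have geometric-series expectations derived independently of the
  engine; agreement is required to 1e-9.
* **Microsimulation.** A vectorized patient-level simulation walks
  individual annual paths through the same decision-tree splits and
  transition probabilities. At 200,000 patients the cohort trace and the
  simulation agree within 3 Monte-Carlo SEs at every cycle and state
  (the SE is floored at one patient so near-empty cells are compared on
  a count basis).
* **Properties.** Occupancy conservation to 1e-9 over 40 cycles,
  absorbing-death monotonicity, discounting inequalities, NMB linearity,
  dominance-quadrant classification on randomized deltas, and bit-for-bit
  PSA reproducibility under a fixed seed.

## What the synthetic inputs do and do not show

The randomized fixtures draw rates within printed 95% CI ranges and
utilities in [0.3, 0.95]; they exercise validation and engine behaviour
across plausible parameter space, not real patient heterogeneity: there
are no SP trajectories, no age structure, no adherence effects, and
response is a binary label. Passing tests therefore demonstrate internal
consistency of the model machinery, not external validity of the
epidemiology.

## Known discrepancies with the published results

With the printed inputs and the calibration above, the model reproduces
the published per-patient QALYs (LC 4.621 vs 4.653; CB 4.435 vs 4.579),
the dominance finding, the NMB (€6,299k vs €6,092k at €30,000/QALY) and
the S3 ICER (€47,110 vs €45,554/QALY) closely. The published *cost
block*, however, is not internally reconstructible from the published
inputs: the LC drug budget of €1,169k implies roughly 420 LC-treated
discounted patient-years at the printed LC price premium, while the
published 108 dialysis-free years require LC responders to persist in
predialysis for well over 570 such years; and the full-future-cost
scenario's totals imply an incremental dialysis-time of ~63 discounted
years where the life-year rows imply ~5. No parameter choice satisfies
both sides. This package reports what the inputs yield — larger LC drug
costs (€2,720k), a smaller cost saving (−€728k vs −€3,875k) and more
dialysis-free years (133 vs 108) — and, downstream, a lower PSA
dominance fraction (~70% vs 99.6%; the cost-effectiveness fraction at
€30,000/QALY remains ≳98%). The direction and decision conclusion (LC
dominant in the base case and in every scenario except S3) are
unaffected.

## Problem sizes

Default analyses use the cohort model (effectively instantaneous); the
PSA runs 1,000 full-model iterations in a few seconds; validation
microsimulations use 30,000–200,000 patients. These sizes are the
package's defaults and match the published analysis where one exists
(1,000 PSA iterations, 1,000-patient cohort).
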