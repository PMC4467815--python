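# phoscea

Cost-effectiveness modelling of phosphate-binder sequencing in chronic
kidney disease (CKD): should patients whose hyperphosphatemia is not
controlled by first-line calcium-based binders (CB: calcium carbonate or
calcium acetate) be switched to second-line lanthanum carbonate (LC), or
kept on CB?

The package is written for health economists and modellers. It implements a
lifetime decision-tree + Markov cohort model from the Spanish public health
care perspective (costs in €, 2013) and everything around it: one-way
scenario analyses, a probabilistic sensitivity analysis (PSA), a
patient-level microsimulation used to validate the cohort engine, and a
small CLI.

## The model

A cohort of 1,000 predialysis CKD patients enters a decision tree that
splits it by treatment response (reaching the serum-phosphorus target,
SP < 4.6 mg/dL):

* **Strategy 1 (continued CB)** — everyone stays on CB regardless of
  response (response rate 44.5% in predialysis, 34.1% in dialysis).
* **Strategy 2 (second-line LC)** — CB non-responders switch to LC
  (response 38.3% / 16.6%); patients still off target after an 8-week LC
  trial switch back to CB.

Each response subgroup then runs through an annual-cycle Markov model over
three states — *predialysis → dialysis → death*, with death absorbing and
no return from dialysis — for up to 40 years. A subgroup's representative
serum phosphorus drives its risks through published SP-stratified tables:

* annual mortality `p = 1 − (1 − p₀)^RR(SP)` with p₀ = 12.3%/yr in
  predialysis and a calibrated baseline in dialysis;
* annual CKD progression `p = 1 − (1 − 0.143)^(1.19^max(0, SP − 4.6))`.

State occupancy is half-cycle corrected; costs (drug acquisition, and
dialysis at €42,555.6 per patient-year) and health outcomes (utilities
0.71 predialysis / 0.61 dialysis, minus a 0.04082 disutility per vomiting
episode on LC) are discounted at 3%/yr. In the base case, dialysis care
falling in a strategy's *added life years* is treated as an unrelated
future cost and excluded; a scenario switch charges full dialysis costs
instead. Strategies are compared by incremental cost, incremental QALYs,
ICER/dominance, and net monetary benefit (NMB) at λ = €30,000/QALY.

## Worked example

```python
from phoscea import default_parameters
from phoscea.economics import evaluate

params = default_parameters()          # bundled base-case inputs
res = evaluate(params)
n = params.settings.cohort_size
print(f"QALYs/patient: CB {res.cb.qalys/n:.3f}, LC {res.lc.qalys/n:.3f}")
print(f"cohort cost difference: EUR {res.ce.delta_cost/1e3:,.0f} thousand")
print(f"dialysis-free years gained: {res.dialysis_free_years_gained:.0f}")
print(res.ce.dominance.value)
```

prints

```
QALYs/patient: CB 4.435, LC 4.621
cohort cost difference: EUR -728 thousand
dialysis-free years gained: 133
dominant
```

i.e. second-line LC delays dialysis by 133 discounted patient-years across
the cohort, gains 0.186 QALYs per patient, and saves money overall —
it *dominates* continued CB. The `examples/` scripts walk through the base
case, the ten one-way scenarios (`run_scenarios.py`; only charging
unrelated future dialysis costs removes dominance, leaving an ICER of
~€47,000/QALY), the PSA (`run_psa.py`) and the microsimulation validation
(`check_against_microsim.py`).

The same analyses are available from a shell:

```bash
phoscea basecase  --out out/base
phoscea scenarios --out out/sens --ids S3,S6
phoscea psa       --out out/psa --n-iter 1000 --seed 7
```

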