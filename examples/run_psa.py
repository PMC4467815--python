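"""Probabilistic sensitivity analysis: joint parameter uncertainty.

Draws 1,000 parameter sets (lognormal costs, binomial response rates at
trial size, normal relative risks, beta utilities), re-runs the model
for each, and summarises where the incremental (cost, QALY) cloud falls
on the cost-effectiveness plane.
"""

from phoscea import default_parameters
from phoscea.sensitivity import PSASpec, run_psa

params = default_parameters()
psa = run_psa(params, PSASpec(n_iterations=1000, seed=params.settings.seed))

print(f"iterations: {psa.n_iterations} (seed {psa.seed})")
print(f"mean incremental cost:  EUR {psa.points['delta_cost'].mean() / 1e3:,.0f} thousand")
print(f"mean incremental QALYs: {psa.points['delta_qalys'].mean():,.1f}")
print(f"fraction dominant (saves money AND gains QALYs): {psa.fraction_dominant:.1%}")
print("cost-effectiveness acceptability:")
for lam, frac in psa.ceac.items():
    print(f"  lambda = EUR {lam:>9,.0f}/QALY -> {frac:.1%} of iterations cost-effective")
print()
print("A point is 'cost-effective' when its net monetary benefit "
      "(lambda x dQALY - dCost) is positive; dominance is the stricter "
      "condition and so its fraction is always the lower bound of the curve.")
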