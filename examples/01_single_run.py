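"""One simulation at a plantation-like demography.

Builds a population of 2000 agents that is 95% Black (of whom 5% are
Mulattos), runs the language game with the standard parameters
(gamma=0.8, delta=0.1, epsilon=0.06) and prints the tail-averaged
language fractions among Mulattos + Bozals.  A creole fraction above 0.8
means the creole C dominates the asymptotic state.
"""

from creolang import ModelParams, init_population, point_to_counts, run
from creolang.phase import DemographicPoint

params = ModelParams(gamma=0.8, delta=0.1, epsilon=0.06)
n_eu, n_m, n_b = point_to_counts(DemographicPoint(x=0.05, y=0.95), 2000)
print(f"demography: {n_eu} Europeans, {n_m} Mulattos, {n_b} Bozals")

state = init_population(n_eu, n_m, n_b)
state, summary, absorbed = run(state, params, seed=1)

print(f"tail-averaged fractions: f_E={summary.f_E:.3f} "
      f"f_A={summary.f_A:.3f} f_C={summary.f_C:.3f}")
print(f"dominant language: {summary.dominant(params.dominance_threshold)}"
      f"  (absorbed to all-E: {absorbed})")
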