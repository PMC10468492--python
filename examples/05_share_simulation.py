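"""Predict share of preference for six hypothetical PrEP programs.

Evaluates each best/worst-case program scenario against the opt-out with
the randomized-first-choice simulator and prints the scenario x segment
share matrix, plus a cost sensitivity sweep.
"""

import cbckit as ck
from cbckit.attributes import COST
from cbckit.mnl import build_arrays

space = ck.default_attributes()
design = ck.generate_design(
    space, ck.default_prohibitions(), n_versions=100, n_tasks=14, n_concepts=2, seed=1
)
population = ck.make_population(ck.default_segments(), seed=2)
dataset = ck.simulate_choices(population, design, seed=3)
arrays = build_arrays(dataset, ck.CodingMap(space))
draws = ck.fit_hb(arrays, ck.HBConfig(n_burn=1500, n_draws=1500, thin=5, seed=4))
estimate = ck.zero_center(draws, ck.CodingMap(space))

scenarios = ck.build_scenarios(space)
names = {i: f"G{i + 1}" for i in range(5)}
report = ck.simulate_shares(
    estimate,
    scenarios,
    population.segment_labels,
    ck.SimConfig(model="rfc", n_draws=500, seed=6),
    group_names=names,
)
print("share of preference (%, program vs no PrEP) by scenario and segment:")
print(report.shares.round(1).to_string())
print("\n(each cell's complement to 100 is the share opting out)")

sweep = ck.sensitivity_table(
    estimate, scenarios[3], COST, ck.SimConfig(model="rfc", n_draws=500, seed=7)
)
print("\ncost sweep on the oral worst-case program:")
print(sweep.to_string(index=False))
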