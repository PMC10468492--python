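"""Simulate a synthetic respondent cohort and run the data-quality funnel.

Draws respondents from the five default preference segments, simulates
their multinomial-logit choices over a generated design, injects
data-quality artifacts (speeders, duplicate origins, straight-liners,
incompletes) plus screened-out entries, and applies the exclusion funnel.
"""

import cbckit as ck

space = ck.default_attributes()
design = ck.generate_design(
    space, ck.default_prohibitions(), n_versions=50, n_tasks=14, n_concepts=2, seed=7
)

population = ck.make_population(ck.default_segments(), seed=7)
print(f"cohort: {population.n_respondents} respondents in "
      f"{len(population.segment_names)} segments")

dataset = ck.simulate_choices(population, design, seed=8)
none_rate = (dataset.tasks["chosen"] == ck.NONE_CHOICE).mean()
print(f"opt-out chosen in {100 * none_rate:.1f}% of tasks")

dataset, injected = ck.inject_artifacts(
    dataset,
    ck.ArtifactConfig(
        speeder_fraction=0.05,
        duplicate_fraction=0.03,
        straightliner_fraction=0.04,
        incomplete_fraction=0.03,
    ),
    seed=9,
)
dataset = ck.add_screenouts(dataset, 120, seed=10)
print(f"injected artifacts: {injected}")

analytic, report = ck.apply_funnel(dataset, min_minutes=10.0)
print("\nexclusion funnel:")
print(report)
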