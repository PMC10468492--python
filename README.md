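# cbckit

Choice-based conjoint (CBC) analysis for stated-preference studies of
health-service delivery, built around a discrete choice experiment on PrEP
(HIV pre-exposure prophylaxis) delivery programs: which dosing method, cost,
clinician interaction, dispensing venue, and initiation burden would make
people actually start PrEP?

The package provides the full analysis chain such a study needs, as a
library:

* **Design engine** — generate survey versions of two-concept-plus-None
  choice tasks satisfying minimal overlap (no level repeats within a task),
  pooled level balance (±1), attribute independence, and feasibility
  prohibitions (e.g. injectable PrEP cannot be mail-delivered); audit any
  design for balance, Cramér's V association, simulated per-level standard
  errors, and relative D-efficiency; the Johnson–Orme rule-of-thumb sample
  size `ceil(500·c/(t·a))`.
* **Synthetic cohort** — respondents drawn from five configurable preference
  segments (default sizes 125/188/115/86/204, N = 718) with known
  coefficients, exact-logit choice simulation, and injectable data-quality
  artifacts, so every estimator can be validated by parameter recovery.
* **QC funnel** — ordered exclusions (ineligible, duplicate origin, speeder,
  straight-liner, incomplete) with an auditable count-per-rule report.
* **Hierarchical Bayes MNL** — Gibbs + random-walk Metropolis estimation of
  respondent-level part-worth utilities β_i ~ N(μ, Σ); zero-centered-diffs
  rescaling (mean attribute range 100) and relative importance scores that
  sum to 100 per respondent.
* **Latent-class MNL** — EM segmentation with multi-start, monotone
  log-likelihood, and CAIC/AIC/BIC class-count selection
  (CAIC = −2LL + p(ln N + 1)).
* **Share simulation** — first-choice, logit, and randomized-first-choice
  predictions of program uptake versus opting out, for six built-in
  best/worst-case program scenarios or user-defined ones, plus sensitivity
  sweeps.
* **Pipeline** — `run_pipeline` chains everything from one seeded config
  into publication-style CSV tables with a run manifest.

See `docs/methods.md` for the models and numerical choices, and `examples/`
for one narrative script per capability.

## Worked example

Estimate part-worth utilities for a synthetic cohort and score attribute
importance (`examples/03_hb_estimation.py`):

```python
import cbckit as ck
from cbckit.mnl import build_arrays

space = ck.default_attributes()
design = ck.generate_design(space, ck.default_prohibitions(),
                            n_versions=100, n_tasks=14, n_concepts=2, seed=1)
population = ck.make_population(ck.default_segments(), seed=2)
dataset = ck.simulate_choices(population, design, seed=3)

coding = ck.CodingMap(space)
arrays = build_arrays(dataset, coding)
draws = ck.fit_hb(arrays, ck.HBConfig(n_burn=2000, n_draws=2000, thin=5, seed=4))
estimate = ck.zero_center(draws, coding)
print(ck.importance_table(estimate, population.segment_labels).round(1))
```

prints (G1–G5 are the five generating segments):

```
mean relative importance scores (%, columns sum to 100):
                       Total    G1    G2    G3    G4    G5
dosing                  35.2  56.5  11.6  47.2  44.0  33.4
cost                    37.2  17.6  65.2  29.2  33.0  29.8
clinician_interaction    7.8   8.3   5.4   9.0   4.1  10.7
dispensing_venue         9.3   9.3   9.2   5.8   5.5  13.1
visit_burden            10.4   8.4   8.6   8.8  13.5  13.0
```

Each column sums to 100: an attribute's score is the share of a
respondent's total utility range it controls, so dosing and cost dominate
uptake decisions overall, while the injectable-focused segment G1 is driven
almost entirely by dosing and the cost-sensitive G2 by price. The
accompanying zero-centered utility table (same script) shows the per-level
preferences behind these scores — e.g. cost enters at ±92.8 for the total
sample — and a large negative opt-out constant for every segment except the
PrEP-averse G4.

The population-mean recovery correlation against the generating
coefficients printed by the script is 0.997.

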