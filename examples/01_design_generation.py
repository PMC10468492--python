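"""Generate and audit a choice-based conjoint design for PrEP delivery.

Builds the five-attribute PrEP space (dosing, cost, clinician interaction,
dispensing venue, visit burden; 13 levels), generates pooled survey
versions of 14 two-concept-plus-None tasks under the injectable-cannot-
be-mailed prohibition, and audits balance, independence, precision, and
D-efficiency.
"""

import cbckit as ck

space = ck.default_attributes()
prohibitions = ck.default_prohibitions()

design = ck.generate_design(
    space, prohibitions, n_versions=100, n_tasks=14, n_concepts=2, seed=42
)
print(f"generated {len(design)} versions x {len(design[0].tasks)} tasks")

diag = ck.audit_design(
    design, space, n_sim_respondents=718, seed=42, prohibitions=prohibitions
)
print("\nlevel occurrence counts (balance within +/-1 per attribute):")
for attr, counts in diag.level_counts.items():
    print(f"  {attr}: {counts}")
print(f"\nmax between-attribute Cramer's V: {diag.max_cramers_v:.3f}  (< 0.05 = independent)")
print(f"relative D-efficiency vs balanced orthogonal ideal: {diag.relative_d_efficiency:.3f}")
print("\nsimulated per-level standard errors (random-choice respondents):")
for label, se in diag.level_standard_errors.items():
    print(f"  {label:<42} {se:.3f}")
print(f"  {'None constant':<42} {diag.none_standard_error:.3f}")

n_min = ck.orme_min_sample(3, 5, 2)
print(f"\nrule-of-thumb minimum sample (3 levels, 5 attributes, 2 concepts): {n_min}")
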