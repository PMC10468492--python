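# Methods

`cbckit` implements the full analysis chain of a choice-based conjoint (CBC)
study of PrEP delivery preferences: experimental design, synthetic
respondents, data-quality filtering, hierarchical Bayes (HB) estimation of
part-worth utilities, latent-class segmentation, and share-of-preference
simulation. This note records the models, the defaults and why they were
chosen, the numerical choices, and the known limitations.

## The choice model

A concept is one program profile: one level per attribute from the
five-attribute space — dosing method (injectable / on-demand / daily oral),
monthly cost (RM 250–350 / RM 125–249), clinician interaction (in-person /
online / text), dispensing venue (courier / mail / pick-up), and visit burden
to start (same day / one-week wait) — 13 levels in total. Each task offers
two concepts plus a "None" opt-out. Respondent *i* chooses alternative *j*
with multinomial-logit probability

    P_ij = exp(u_ij) / Σ_k exp(u_ik),   u_ij = x_j' β_i,

where `x_j` is the effects-coded profile (sum-to-zero within each attribute,
last level as the negative reference) and the opt-out is an
alternative-specific constant. The default geometry yields 8 free level
columns plus the None column: p = 9 coded coefficients per respondent.

## Survey design engine

Designs follow three principles: minimal overlap (no level repeats within a
task), level balance (pooled counts within ±1 of equal), and independence
across attributes. Levels are assigned per attribute by a quota-greedy
sampler — each task takes the levels with the largest remaining quotas, with
random tie-breaking — which guarantees balance and overlap by construction;
prohibited combinations (by default only injectable × mail delivery) are then
removed by randomized swaps that preserve both properties. Strict minimal
overlap requires at least as many levels as concepts per attribute; a
`relax_overlap` switch degrades gracefully to minimized overlap otherwise.

The audit simulates respondents cycling over versions who answer uniformly
at random (opt-out included), fits one aggregate effects-coded MNL by
Newton–Raphson, and reports the standard error of every expanded level
utility. Independence is measured by pairwise Cramér's V (flagged above
0.05); for pairs carrying a prohibition the expected counts come from a
quasi-independence model (iterative proportional fitting on the allowed
cells) so the structural zero is not charged to the design. Relative
D-efficiency is `(det I_design / det I_ideal)^(1/p)` of per-task Fisher
information at null coefficients, where the ideal is the balanced orthogonal
design (block-diagonal information computed by enumerating equally likely
level subsets per attribute). A level that never appears makes the
information singular; the audit names the level instead of failing.

Under this audit the realized per-level standard errors at the full study
scale (650 versions, 718 simulated respondents, 14 tasks) are 0.012 for
2-level and 0.019–0.022 for 3-level attributes — i.e. comfortably below the
field's 0.05 rule of thumb. The closed forms are `sqrt(1.5/n_tasks)` and
`sqrt(3.6/n_tasks)`: per-task Fisher information at β = 0 is 2/3 for a binary
effects column and the 2×2 block [[10/27, 5/27], [5/27, 10/27]] for a 3-level
attribute, whose inverse has 3.6 on the diagonal in level-utility space.

The Johnson–Orme sample-size rule of thumb is `ceil(500·c/(t·a))` with `c`
the largest level count; with c = 3, t = 5, a = 2 it gives 150.

## Synthetic cohort

The generator emulates a 718-respondent cohort in five preference segments
(sizes 125/188/115/86/204): injectable-focused, cost-dominated,
on-demand-averse, PrEP-averse (positive opt-out utility), and
on-demand-oriented. Segment mean utilities are specified on the zero-centered
display scale and divided by `logit_scale` (default 50) to obtain raw logit
coefficients; two of the reference clinician-interaction columns carry a ±0.1
rounding residue and are re-centered exactly. Respondent heterogeneity is
i.i.d. normal noise with standard deviation `spread` (default 0.5) on each
coded coefficient — drawing noise in coded space keeps within-attribute
utilities exactly zero-sum. The divisor and spread are conventions, not
estimates: the raw logit scale of zero-centered utilities is unrecoverable from
zero-centered scores, and 50 places choice consistency in a realistic (high)
range while 0.5 gives heterogeneity comparable to the smaller attribute
effects.

Choices are drawn from the exact logit probabilities. Baseline completion
times are uniform on 12–25 minutes and origin identifiers unique, so quality
artifacts exist only where injected: speeders (time below 10 minutes),
duplicate origins, straight-liners (same alternative in all tasks),
incompletes (trailing half of tasks blanked). Artifact subsets are drawn
disjointly so injected counts equal funnel removals exactly; screened-out
(ineligible) entries can be appended as metadata-only rows.

What the generator does **not** emulate: demographic/behavioral covariates,
context or fatigue effects across the 14 tasks, non-logit decision rules
(e.g. attribute non-attendance), and within-segment correlation structure
beyond diagonal noise. Passing recovery tests therefore demonstrates
estimator correctness under the assumed model, not robustness to real survey
behavior.

## Data-quality funnel

Rules run in a fixed order — ineligible, duplicate origin (first occurrence
kept), speeder (< 10 minutes), straight-liner, incomplete — and each removed
respondent is counted once under the first rule that catches them. Totals
are order-invariant; the per-rule breakdown is not, which is why the order is
part of the contract. "Straight-liner" means every task answered and the same
alternative position chosen throughout. Rates are reported at one decimal:
eligible/opened and excluded/eligible.

## Hierarchical Bayes estimation

Respondent coefficients follow β_i ~ N(μ, Σ) with conjugate priors
μ ~ N(0, 100·I) and Σ ~ Inverse-Wishart(p + 5, I). The sampler is Gibbs over
(μ | β, Σ) and (Σ | β, μ) with a joint random-walk Metropolis step per
respondent (proposal: current-Σ Cholesky scaled per respondent), adapted
toward 0.3 acceptance during burn-in only, so kept draws form a valid chain.
Chains start at the aggregate MNL fit. Defaults: 10,000 burn-in, 10,000 kept,
thin 10; a split-chain R̂ on μ is reported. Point estimates are posterior
means of respondent coefficients.

Zero-centered diffs: coded coefficients are expanded to all 13 level
utilities plus the opt-out constant, and each respondent is rescaled so the
mean within-attribute range is 100 (total range 500 over five attributes);
the same multiplier applies to the opt-out. An all-flat respondent keeps
multiplier 1 with a warning. Relative importance (RIS) of an attribute is its
range divided by the respondent's summed ranges × 100, so respondent RIS sums
to 100 exactly and group tables (means of respondent RIS) do too.

Known limitations, visible in the study-scale recovery checks:

* The opt-out population mean is only bounded from above by respondents who
  never opt out, so its posterior magnitude is weakly identified and settles
  well below the generating value (sign and orderings are unaffected).
* Minimal overlap puts both cost levels in every task, so respondents with
  dominant cost preferences choose almost deterministically on cost and
  carry little information about other attributes; their other coefficients
  shrink toward the population center. Together with covariance-based
  imputation for respondents who nearly always opt out, this biases
  small-magnitude population-mean coordinates (notably injectable dosing)
  toward zero even though the overall population-mean correlation with the
  generating truth exceeds 0.99. A unimodal normal population cannot remove
  this: it is a property of near-deterministic mixture data, not of chain
  length.

## Latent-class segmentation

A K-class mixture of MNLs fitted by EM: the E-step computes membership
posteriors from class shares × respondent likelihoods; the M-step reweights
shares and runs a few damped Newton iterations per class (an ECM step, so
the observed-data log-likelihood never decreases — asserted every
iteration). Starts are perturbations of the aggregate fit (default 20;
selection studies here use 3–5, which suffice at this separation); K = 1
reduces exactly to the aggregate fit. Emptying classes are re-seeded once
with a warning. Model selection reports LL, AIC, BIC and CAIC
(−2LL + p(ln N + 1), N = respondents, p = K·9 + K − 1) and picks the
CAIC-minimizing K; on the default cohort that is K = 5, recovering the
generating segments (ARI > 0.8, sizes within 10%).

## Share-of-preference simulation

Each hypothetical program (six best/worst-case scenarios across the three
dosing methods are built in) is evaluated one-at-a-time against the opt-out
on the raw logit scale; zero-centered values are display-only. Simulators:
first choice (strict dominance; exact ties split 50/50), logit expectation,
and randomized first choice (RFC). Per RFC draw, every coded part-worth gets
independent normal "attribute" error with scale `attribute_error_scale` ×
the cohort's per-coordinate standard deviation (default 0.5), each
alternative's total utility gets extreme-value "product" error (scale 1.0),
and the highest composite utility wins; shares average over draws (default
1,000) and respondents. Program share and opt-out share sum to 100 exactly
per cell, RFC converges to first choice as both scales → 0, and Monte-Carlo
error shrinks as draws^(−1/2). The commercial simulators' error magnitudes
are unpublished, so both scales are exposed and recorded in the report
metadata. Sensitivity sweeps substitute each level of one attribute into a
base scenario, flagging prohibited combinations instead of simulating them.

## Pipeline and reproducibility

`run_pipeline` executes every stage from one config with a single global
seed; per-stage seeds are derived via `SeedSequence`, logged in a manifest,
and all CSV artifacts are byte-stable for a fixed config. Every stochastic
component (design, cohort, artifacts, HB, EM starts, RFC) takes an explicit
seed and uses its own `numpy` generator.

Problem sizes used by the shipped checks are the package's own choices: the
study-scale checks use the full 650-version design and the 718-respondent
cohort with HB chains of 3,000 + 3,000 (the bias structure above is
unchanged at 10,000 + 10,000); the acceptance script estimates a one-fifth
cohort (144 respondents, 72 versions) since the quantities it reports are
scale-invariant by construction.
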