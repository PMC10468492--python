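"""Choice-based conjoint survey design generation and auditing.

Designs follow three principles: (1) minimal overlap — within a choice task
no attribute level appears in more than one concept; (2) level balance —
pooled across the whole design, each level of an attribute appears as close
to equally often as possible; (3) independence — levels are assigned
independently across attributes.  Prohibited (infeasible) level
combinations are repaired by targeted swaps that preserve balance and
minimal overlap.

The audit simulates random-choice respondents over the emitted design, fits
an aggregate effects-coded multinomial logit, and reports per-level
standard errors along with level counts, between-attribute association
(Cramer's V), and relative D-efficiency versus the balanced orthogonal
ideal.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .attributes import (
    AttributeSpace,
    Concept,
    ConfigurationError,
    Prohibition,
)
from .coding import CodingMap
from .mnl import fit_mnl, level_utility_covariance


class InfeasibleDesignError(ValueError):
    """Raised when the prohibition set leaves no legal design."""


@dataclass(frozen=True)
class Task:
    """One choice task: a fixed number of concepts plus an optional opt-out."""

    concepts: tuple[Concept, ...]
    include_none: bool = True


@dataclass(frozen=True)
class SurveyVersion:
    """One survey version: an ordered list of choice tasks."""

    version_id: int
    tasks: tuple[Task, ...]


@dataclass
class DesignDiagnostics:
    """Audit results for an emitted design."""

    level_counts: dict[str, dict[str, int]]
    cramers_v: dict[tuple[str, str], float]
    level_standard_errors: dict[str, float]
    none_standard_error: float | None
    relative_d_efficiency: float
    confounded_levels: list[str] = field(default_factory=list)
    singular: bool = False

    @property
    def max_cramers_v(self) -> float:
        return max(self.cramers_v.values()) if self.cramers_v else 0.0


# ---- sample-size rule ---------------------------------------------------------


def orme_min_sample(largest_levels: int, t: int, a: int) -> int:
    """Johnson-Orme rule-of-thumb minimum sample size: ceil(500 c / (t a)).

    ``largest_levels`` is the largest number of levels in any attribute,
    ``t`` the relevant task/attribute count, and ``a`` the number of
    alternatives (concepts) per task.
    """
    for name, v in (("largest_levels", largest_levels), ("t", t), ("a", a)):
        if int(v) != v or v < 1:
            raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
    return math.ceil(500 * largest_levels / (t * a))


# ---- generation ---------------------------------------------------------------


def _legal_pairs_mask(
    space: AttributeSpace, prohibitions: Sequence[Prohibition]
) -> dict[tuple[int, int], np.ndarray]:
    """Boolean allow-matrix per ordered attribute pair with a prohibition."""
    masks: dict[tuple[int, int], np.ndarray] = {}
    for p in prohibitions:
        ia, la, ib, lb = p.as_indices(space)
        key = (min(ia, ib), max(ia, ib))
        if key not in masks:
            masks[key] = np.ones(
                (space.attributes[key[0]].n_levels, space.attributes[key[1]].n_levels),
                dtype=bool,
            )
        if ia < ib:
            masks[key][la, lb] = False
        else:
            masks[key][lb, la] = False
    return masks


def _check_feasibility(space: AttributeSpace, prohibitions: Sequence[Prohibition]) -> None:
    """Every level of every attribute must admit at least one legal full concept."""
    masks = _legal_pairs_mask(space, prohibitions)

    def legal(levels: dict[int, int]) -> bool:
        for (i, j), m in masks.items():
            if i in levels and j in levels and not m[levels[i], levels[j]]:
                return False
        return True

    def extend(levels: dict[int, int], remaining: list[int]) -> bool:
        if not remaining:
            return True
        ai = remaining[0]
        for lev in range(space.attributes[ai].n_levels):
            levels[ai] = lev
            if legal(levels) and extend(levels, remaining[1:]):
                del levels[ai]
                return True
            del levels[ai]
        return False

    for ai, attr in enumerate(space):
        for lev in range(attr.n_levels):
            others = [i for i in range(len(space)) if i != ai]
            if not extend({ai: lev}, others):
                raise InfeasibleDesignError(
                    f"prohibitions leave no legal concept containing "
                    f"{attr.name!r} = {attr.levels[lev]!r}"
                )


def _task_ok(task_levels: np.ndarray, n_levels: int, strict: bool) -> bool:
    counts = np.bincount(task_levels, minlength=n_levels)
    if strict:
        return counts.max() <= 1
    cap = math.ceil(len(task_levels) / n_levels)
    return counts.max() <= cap


def _quota_greedy_levels(
    n_levels: int, n_tasks: int, n_concepts: int, rng: np.random.Generator
) -> np.ndarray:
    """Level assignments (n_tasks, n_concepts) satisfying overlap and balance.

    Each task takes the ``n_concepts`` levels with the largest remaining
    quotas (random tie-breaking), which keeps pooled counts within one of
    perfect balance at every step and never repeats a level within a task
    when ``n_concepts <= n_levels``; when it exceeds it, levels are tiled
    so per-task counts differ by at most one (minimized overlap).
    """
    per_task_full, extra = divmod(n_concepts, n_levels)
    quota = np.zeros(n_levels)  # higher = more owed
    out = np.empty((n_tasks, n_concepts), dtype=int)
    for t in range(n_tasks):
        ranks = np.argsort(-(quota + rng.random(n_levels)), kind="stable")
        picked = ranks[:extra] if extra else np.empty(0, dtype=int)
        row = np.concatenate([np.tile(np.arange(n_levels), per_task_full), picked])
        quota += n_concepts / n_levels
        np.subtract.at(quota, row, 1.0)
        out[t] = rng.permutation(row)
    return out


def _repair_prohibitions(
    levels: np.ndarray,
    space: AttributeSpace,
    prohibitions: Sequence[Prohibition],
    strict: bool,
    rng: np.random.Generator,
    n_concepts: int,
) -> None:
    """In-place swap repair removing prohibited level co-occurrences.

    ``levels`` has shape (n_tasks_total, n_concepts, n_attrs).  For each
    violating concept we swap the second attribute's level with another
    concept elsewhere such that no prohibition is violated on either side
    and both tasks keep the overlap rule for that attribute.
    """
    idx = [p.as_indices(space) for p in prohibitions]

    def concept_legal(task: int, con: int) -> bool:
        for ia, la, ib, lb in idx:
            if levels[task, con, ia] == la and levels[task, con, ib] == lb:
                return False
        return True

    n_tasks = levels.shape[0]
    for _pass in range(200):
        violations = [
            (t, c)
            for t in range(n_tasks)
            for c in range(n_concepts)
            if not concept_legal(t, c)
        ]
        if not violations:
            return
        # shared cycling pointer: each donor candidate is scanned O(1) times
        order = rng.permutation(n_tasks)
        g = 0
        budget = 2 * n_tasks
        for t, c in violations:
            if concept_legal(t, c):
                continue
            # pick the prohibited pair and swap attribute ib's level away
            for ia, la, ib, lb in idx:
                if levels[t, c, ia] == la and levels[t, c, ib] == lb:
                    break
            nb = space.attributes[ib].n_levels
            fixed = False
            tried = 0
            while not fixed and tried < budget:
                t2 = order[g % n_tasks]
                g += 1
                tried += 1
                if t2 == t:
                    continue
                for c2 in range(n_concepts):
                    if levels[t2, c2, ib] == lb:
                        continue
                    levels[t, c, ib], levels[t2, c2, ib] = (
                        levels[t2, c2, ib],
                        levels[t, c, ib],
                    )
                    ok = (
                        concept_legal(t, c)
                        and concept_legal(t2, c2)
                        and _task_ok(levels[t, :, ib], nb, strict)
                        and _task_ok(levels[t2, :, ib], nb, strict)
                    )
                    if ok:
                        fixed = True
                        break
                    levels[t, c, ib], levels[t2, c2, ib] = (
                        levels[t2, c2, ib],
                        levels[t, c, ib],
                    )
    remaining = [
        (t, c)
        for t in range(n_tasks)
        for c in range(n_concepts)
        if not concept_legal(t, c)
    ]
    if remaining:
        raise InfeasibleDesignError(
            f"could not repair {len(remaining)} prohibited concept(s); "
            "the prohibition set may be unsatisfiable for this geometry"
        )


def generate_design(
    space: AttributeSpace,
    prohibitions: Sequence[Prohibition] = (),
    n_versions: int = 650,
    n_tasks: int = 14,
    n_concepts: int = 2,
    seed: int = 0,
    include_none: bool = True,
    relax_overlap: bool = False,
) -> list[SurveyVersion]:
    """Generate survey versions satisfying overlap, balance, and independence.

    Each attribute's levels are assigned independently from a globally
    balanced shuffled pool, then repaired: first so that no level repeats
    within a task (strict minimal overlap; set ``relax_overlap=True`` to
    allow the minimum possible overlap when ``n_concepts`` exceeds an
    attribute's level count), then so that no concept violates a
    prohibition.  All repairs are swaps, so pooled level counts stay within
    one of perfect balance.  Deterministic for a fixed ``seed``.
    """
    space.validate_prohibitions(prohibitions)
    if n_versions < 1 or n_tasks < 1 or n_concepts < 1:
        raise ConfigurationError("n_versions, n_tasks, n_concepts must be >= 1")
    min_levels = min(space.level_counts)
    if n_concepts > min_levels and not relax_overlap:
        raise ConfigurationError(
            f"strict minimal overlap impossible: {n_concepts} concepts per task "
            f"but smallest attribute has {min_levels} levels; "
            "set relax_overlap=True to minimize rather than forbid overlap"
        )
    if prohibitions:
        _check_feasibility(space, prohibitions)

    rng = np.random.default_rng(seed)
    total_tasks = n_versions * n_tasks
    n_attrs = len(space)
    levels = np.zeros((total_tasks, n_concepts, n_attrs), dtype=int)
    for ai, attr in enumerate(space):
        levels[:, :, ai] = _quota_greedy_levels(
            attr.n_levels, total_tasks, n_concepts, rng
        )
    if prohibitions:
        strict = n_concepts <= min_levels
        _repair_prohibitions(levels, space, prohibitions, strict, rng, n_concepts)

    versions = []
    for v in range(n_versions):
        tasks = []
        for t in range(n_tasks):
            row = levels[v * n_tasks + t]
            tasks.append(
                Task(
                    concepts=tuple(Concept(tuple(int(x) for x in row[c])) for c in range(n_concepts)),
                    include_none=include_none,
                )
            )
        versions.append(SurveyVersion(version_id=v, tasks=tuple(tasks)))
    return versions


# ---- serialization ------------------------------------------------------------


def design_to_json(
    versions: Sequence[SurveyVersion],
    space: AttributeSpace,
    prohibitions: Sequence[Prohibition] = (),
    path: str | Path | None = None,
) -> str:
    payload = {
        "attributes": [{"name": a.name, "levels": list(a.levels)} for a in space],
        "prohibitions": [
            [p.attr_a, p.level_a, p.attr_b, p.level_b] for p in prohibitions
        ],
        "versions": [
            {
                "version_id": v.version_id,
                "tasks": [
                    {
                        "concepts": [list(c.levels) for c in t.concepts],
                        "none": t.include_none,
                    }
                    for t in v.tasks
                ],
            }
            for v in versions
        ],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def design_from_json(
    source: str | Path,
) -> tuple[list[SurveyVersion], AttributeSpace, list[Prohibition]]:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    from .attributes import Attribute

    space = AttributeSpace(
        tuple(Attribute(a["name"], tuple(a["levels"])) for a in payload["attributes"])
    )
    prohibitions = [Prohibition(*p) for p in payload["prohibitions"]]
    versions = [
        SurveyVersion(
            version_id=v["version_id"],
            tasks=tuple(
                Task(
                    concepts=tuple(Concept(tuple(c)) for c in t["concepts"]),
                    include_none=bool(t["none"]),
                )
                for t in v["tasks"]
            ),
        )
        for v in payload["versions"]
    ]
    return versions, space, prohibitions


# ---- audit --------------------------------------------------------------------


def pooled_levels(versions: Sequence[SurveyVersion], space: AttributeSpace) -> np.ndarray:
    """All shown concepts as an int array of shape (n_concepts_total, n_attrs)."""
    rows = [
        c.levels for v in versions for t in v.tasks for c in t.concepts
    ]
    return np.asarray(rows, dtype=int)


def level_count_table(
    versions: Sequence[SurveyVersion], space: AttributeSpace
) -> dict[str, dict[str, int]]:
    pool = pooled_levels(versions, space)
    out: dict[str, dict[str, int]] = {}
    for ai, attr in enumerate(space):
        counts = np.bincount(pool[:, ai], minlength=attr.n_levels)
        out[attr.name] = {lev: int(c) for lev, c in zip(attr.levels, counts)}
    return out


def cramers_v_table(
    versions: Sequence[SurveyVersion],
    space: AttributeSpace,
    prohibitions: Sequence[Prohibition] = (),
) -> dict[tuple[str, str], float]:
    """Pairwise Cramer's V between attribute level assignments over the pool.

    Cells removed by a prohibition are structural zeros: for such pairs the
    expected counts come from a quasi-independence model (margins fitted to
    the allowed cells by iterative proportional fitting) and the prohibited
    cells are excluded, so the statistic measures only avoidable
    association.
    """
    pool = pooled_levels(versions, space)
    n = len(pool)
    masks = _legal_pairs_mask(space, prohibitions)
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(space)), 2):
        ni, nj = space.attributes[i].n_levels, space.attributes[j].n_levels
        obs = np.zeros((ni, nj))
        np.add.at(obs, (pool[:, i], pool[:, j]), 1.0)
        allowed = masks.get((i, j), np.ones((ni, nj), dtype=bool))
        if allowed.all():
            exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / n
        else:
            # IPF on the allowed cells to the observed margins
            exp = allowed.astype(float)
            row_m, col_m = obs.sum(axis=1), obs.sum(axis=0)
            for _ in range(200):
                rs = exp.sum(axis=1)
                exp *= np.where(rs > 0, row_m / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
                cs = exp.sum(axis=0)
                exp *= np.where(cs > 0, col_m / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        chi2 = float(contrib[allowed].sum())
        v = math.sqrt(chi2 / (n * (min(ni, nj) - 1)))
        out[(space.attributes[i].name, space.attributes[j].name)] = v
    return out


def _per_task_information(
    versions: Sequence[SurveyVersion], coding: CodingMap
) -> np.ndarray:
    """Average per-task Fisher information at beta = 0 (uniform choice)."""
    p = coding.n_params
    info = np.zeros((p, p))
    n_tasks = 0
    for v in versions:
        for t in v.tasks:
            rows = [coding.encode_concept(c.levels) for c in t.concepts]
            if t.include_none:
                rows.append(coding.encode_none())
            X = np.asarray(rows)
            probs = np.full(len(rows), 1.0 / len(rows))
            xbar = probs @ X
            info += (X.T * probs) @ X - np.outer(xbar, xbar)
            n_tasks += 1
    return info / n_tasks


def _ideal_information(coding: CodingMap, n_concepts: int, include_none: bool) -> np.ndarray:
    """Per-task Fisher information of the balanced orthogonal ideal at beta = 0.

    Attributes contribute independent blocks computed by enumerating all
    equally likely draws of ``n_concepts`` distinct levels; the opt-out
    constant contributes a scalar block; cross terms vanish by independence
    and balance.
    """
    p = coding.n_params
    n_alt = n_concepts + (1 if include_none else 0)
    prob = 1.0 / n_alt
    info = np.zeros((p, p))
    for attr, sl in zip(coding.space, coding.attr_slices()):
        L = attr.n_levels
        k = sl.stop - sl.start
        block = np.zeros((k, k))
        combos = list(itertools.combinations(range(L), min(n_concepts, L)))
        for combo in combos:
            X = np.zeros((n_alt, k))
            for row, lev in enumerate(combo):
                if lev < L - 1:
                    X[row, lev] = 1.0
                else:
                    X[row, :] = -1.0
            probs = np.full(n_alt, prob)
            xbar = probs @ X
            block += (X.T * probs) @ X - np.outer(xbar, xbar)
        info[sl, sl] = block / len(combos)
    if include_none:
        info[coding.none_col, coding.none_col] = prob * (1 - prob)
    return info


def relative_d_efficiency(
    versions: Sequence[SurveyVersion], space: AttributeSpace
) -> float:
    """Relative D-efficiency of the realized design versus the balanced ideal.

    Both information matrices are per-task averages evaluated at null
    coefficients; the ratio of determinants is raised to 1/p.
    """
    include_none = versions[0].tasks[0].include_none
    n_concepts = len(versions[0].tasks[0].concepts)
    coding = CodingMap(space, include_none=include_none)
    realized = _per_task_information(versions, coding)
    ideal = _ideal_information(coding, n_concepts, include_none)
    sign_r, logdet_r = np.linalg.slogdet(realized)
    sign_i, logdet_i = np.linalg.slogdet(ideal)
    if sign_r <= 0:
        return 0.0
    return float(np.exp((logdet_r - logdet_i) / coding.n_params))


def audit_design(
    versions: Sequence[SurveyVersion],
    space: AttributeSpace,
    n_sim_respondents: int = 718,
    seed: int = 0,
    prohibitions: Sequence[Prohibition] = (),
) -> DesignDiagnostics:
    """Audit an emitted design: counts, association, simulated SEs, efficiency.

    Simulated standard errors follow the standard design test: assign
    ``n_sim_respondents`` respondents to versions by cycling, draw uniformly
    random choices over each task's alternatives (including the opt-out),
    fit one aggregate effects-coded MNL, and report the standard error of
    each expanded level utility.
    """
    if not versions:
        raise ConfigurationError("design is empty")
    counts = level_count_table(versions, space)
    confounded = [
        f"{attr}:{lev}"
        for attr, levs in counts.items()
        for lev, c in levs.items()
        if c == 0
    ]
    vtable = cramers_v_table(versions, space, prohibitions)
    include_none = versions[0].tasks[0].include_none
    coding = CodingMap(space, include_none=include_none)

    rng = np.random.default_rng(seed)
    X_rows, chosen = [], []
    n_alt = len(versions[0].tasks[0].concepts) + (1 if include_none else 0)
    # precompute encoded tasks per version
    encoded = []
    for v in versions:
        enc_v = []
        for t in v.tasks:
            rows = [coding.encode_concept(c.levels) for c in t.concepts]
            if t.include_none:
                rows.append(coding.encode_none())
            enc_v.append(np.asarray(rows))
        encoded.append(enc_v)
    for r in range(n_sim_respondents):
        for enc in encoded[r % len(versions)]:
            X_rows.append(enc)
            chosen.append(rng.integers(len(enc)))
    X = np.stack(X_rows)
    chosen_arr = np.asarray(chosen)

    singular = bool(confounded)
    if singular:
        ses = {lab: float("nan") for lab in coding.level_labels()}
        none_se = float("nan") if include_none else None
    else:
        fit = fit_mnl(X, chosen_arr)
        singular = fit.singular
        lev_cov = level_utility_covariance(fit.cov, coding)
        lev_se = np.sqrt(np.diag(lev_cov))
        labels = coding.level_labels()
        ses = {lab: float(se) for lab, se in zip(labels, lev_se)}
        none_se = float(lev_se[-1]) if include_none else None

    return DesignDiagnostics(
        level_counts=counts,
        cramers_v=vtable,
        level_standard_errors=ses,
        none_standard_error=none_se,
        relative_d_efficiency=relative_d_efficiency(versions, space),
        confounded_levels=confounded,
        singular=singular,
    )
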