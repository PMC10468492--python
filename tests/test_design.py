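"""Design engine: overlap, balance, independence, prohibitions, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cbckit as ck
from cbckit.attributes import Attribute, AttributeSpace, Concept
from cbckit.design import (
    Task,
    cramers_v_table,
    level_count_table,
    pooled_levels,
    relative_d_efficiency,
)


def assert_overlap_and_prohibitions(design, space, prohibitions):
    for v in design:
        for t in v.tasks:
            for ai in range(len(space)):
                levs = [c.levels[ai] for c in t.concepts]
                assert len(set(levs)) == len(levs), "level repeated within a task"
            for c in t.concepts:
                assert not c.violates(space, prohibitions)


def assert_balance(design, space):
    for attr, counts in level_count_table(design, space).items():
        vals = list(counts.values())
        assert max(vals) - min(vals) <= 1, f"imbalance in {attr}: {counts}"


@pytest.mark.parametrize(
    "c, t, a, expected",
    [
        (3, 5, 2, 150),  # five-attribute, three-level, two-choice rule of thumb
        (1, 500, 1, 1),
        (3, 14, 2, 54),  # ceil(1500 / 28)
    ],
)
def test_min_sample_rule(c, t, a, expected):
    assert ck.orme_min_sample(c, t, a) == expected


def test_min_sample_rule_rejects_bad_arguments():
    with pytest.raises(ck.ConfigurationError):
        ck.orme_min_sample(0, 5, 2)
    with pytest.raises(ck.ConfigurationError):
        ck.orme_min_sample(3, 5, 0)


def test_single_binary_attribute_task_shows_both_levels(binary_space):
    design = ck.generate_design(
        binary_space, n_versions=1, n_tasks=1, n_concepts=2, seed=0
    )
    task = design[0].tasks[0]
    shown = sorted(c.levels[0] for c in task.concepts)
    assert shown == [0, 1]


def test_three_by_three_pool_balances_to_sixty_each():
    """90 pooled tasks x 2 concepts over 3-level attributes -> 60 per level +/- 1."""
    space = AttributeSpace(
        tuple(Attribute(f"a{i}", ("x", "y", "z")) for i in range(3))
    )
    design = ck.generate_design(space, n_versions=9, n_tasks=10, n_concepts=2, seed=7)
    # independent brute-force tally over the emitted design
    tally = {}
    for v in design:
        for t in v.tasks:
            for c in t.concepts:
                for ai, lev in enumerate(c.levels):
                    tally[(ai, lev)] = tally.get((ai, lev), 0) + 1
    assert sum(tally.values()) == 9 * 10 * 2 * 3
    for count in tally.values():
        assert 59 <= count <= 61


def test_default_design_constraints(space, prohibitions, small_design):
    assert len(small_design) == 30
    assert all(len(v.tasks) == 14 for v in small_design)
    assert_overlap_and_prohibitions(small_design, space, prohibitions)
    assert_balance(small_design, space)


def test_design_determinism(space, prohibitions):
    kw = dict(n_versions=8, n_tasks=14, n_concepts=2)
    d1 = ck.generate_design(space, prohibitions, seed=42, **kw)
    d2 = ck.generate_design(space, prohibitions, seed=42, **kw)
    d3 = ck.generate_design(space, prohibitions, seed=43, **kw)
    assert ck.design_to_json(d1, space) == ck.design_to_json(d2, space)
    assert ck.design_to_json(d1, space) != ck.design_to_json(d3, space)


def test_design_json_round_trip(space, prohibitions, small_design, tmp_path):
    path = tmp_path / "design.json"
    ck.design_to_json(small_design, space, prohibitions, path)
    versions, space2, proh2 = ck.design_from_json(path)
    assert space2 == space
    assert list(proh2) == list(prohibitions)
    assert versions == list(small_design)


def test_too_many_concepts_requires_relaxation(binary_space):
    with pytest.raises(ck.ConfigurationError, match="relax_overlap"):
        ck.generate_design(binary_space, n_versions=1, n_tasks=4, n_concepts=3, seed=0)
    design = ck.generate_design(
        binary_space, n_versions=1, n_tasks=4, n_concepts=3, seed=0, relax_overlap=True
    )
    for t in design[0].tasks:  # minimized overlap: per-task counts differ by <= 1
        counts = np.bincount([c.levels[0] for c in t.concepts], minlength=2)
        assert counts.max() - counts.min() <= 1


def test_unsatisfiable_prohibitions_raise(space):
    dosing = space.attributes[0]
    venue = space.attributes[3]
    blocked = [
        ck.Prohibition(dosing.name, dosing.levels[0], venue.name, lev)
        for lev in venue.levels
    ]
    with pytest.raises(ck.InfeasibleDesignError):
        ck.generate_design(space, blocked, n_versions=2, n_tasks=4, n_concepts=2, seed=0)


def test_full_factorial_two_by_two_has_unit_efficiency():
    """Both minimal-overlap pairings shown equally -> D-efficiency exactly 1."""
    space = AttributeSpace(
        (Attribute("a", ("a0", "a1")), Attribute("b", ("b0", "b1")))
    )
    t1 = Task((Concept((0, 0)), Concept((1, 1))))
    t2 = Task((Concept((0, 1)), Concept((1, 0))))
    design = [ck.SurveyVersion(0, (t1, t2))]
    assert relative_d_efficiency(design, space) == pytest.approx(1.0, abs=1e-12)


def test_prohibition_never_increases_efficiency(space, prohibitions):
    kw = dict(n_versions=40, n_tasks=14, n_concepts=2, seed=11)
    free = ck.generate_design(space, (), **kw)
    constrained = ck.generate_design(space, prohibitions, **kw)
    assert relative_d_efficiency(constrained, space) <= relative_d_efficiency(
        free, space
    ) + 1e-9


def test_attribute_independence_on_pooled_design(space, prohibitions):
    design = ck.generate_design(
        space, prohibitions, n_versions=100, n_tasks=14, n_concepts=2, seed=5
    )
    vt = cramers_v_table(design, space, prohibitions)
    assert max(vt.values()) < 0.05


def test_absent_level_reported_as_confounded(space):
    """A design never showing one level is flagged by name, not a silent failure."""
    base = ck.generate_design(space, n_versions=4, n_tasks=14, n_concepts=2, seed=3)
    # rewrite every text-based consult (clinician level 2) to online (level 1)
    broken = []
    for v in base:
        tasks = []
        for t in v.tasks:
            cons = []
            for c in t.concepts:
                levs = list(c.levels)
                if levs[2] == 2:
                    levs[2] = 1
                cons.append(Concept(tuple(levs)))
            tasks.append(Task(tuple(cons), t.include_none))
        broken.append(ck.SurveyVersion(v.version_id, tuple(tasks)))
    diag = ck.audit_design(broken, space, n_sim_respondents=40, seed=0)
    assert diag.singular
    assert "clinician_interaction:Text-based" in diag.confounded_levels


def test_audit_reports_counts_consistent_with_pool(space, prohibitions, small_design):
    diag = ck.audit_design(
        small_design, space, n_sim_respondents=50, seed=9, prohibitions=prohibitions
    )
    pool = pooled_levels(small_design, space)
    for ai, attr in enumerate(space):
        assert sum(diag.level_counts[attr.name].values()) == len(pool)
    assert 0.0 < diag.relative_d_efficiency <= 1.0
    assert all(np.isfinite(v) for v in diag.level_standard_errors.values())


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n_levels=st.integers(2, 4),
    n_attrs=st.integers(1, 3),
    n_tasks=st.integers(2, 10),
    seed=st.integers(0, 100),
)
def test_overlap_and_balance_hold_for_random_geometries(
    n_levels, n_attrs, n_tasks, seed
):
    space = AttributeSpace(
        tuple(
            Attribute(f"a{i}", tuple(f"l{j}" for j in range(n_levels)))
            for i in range(n_attrs)
        )
    )
    design = ck.generate_design(
        space, n_versions=3, n_tasks=n_tasks, n_concepts=2, seed=seed
    )
    assert_overlap_and_prohibitions(design, space, ())
    assert_balance(design, space)
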