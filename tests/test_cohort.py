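"""Synthetic cohort generator: sizes, choice law, artifacts, determinism."""

import numpy as np
import pytest

import cbckit as ck
from cbckit.attributes import Attribute, AttributeSpace
from cbckit.cohort import SegmentDefinition
from cbckit.dataset import NONE_CHOICE
from cbckit.design import Task
from cbckit.attributes import Concept


def one_attr_space():
    return AttributeSpace((Attribute("a", ("hi", "lo")),))


def one_task_design(include_none=True):
    return [
        ck.SurveyVersion(0, (Task((Concept((0,)), Concept((1,))), include_none),))
    ]


def test_default_population_has_default_segment_sizes():
    pop = ck.make_population(ck.default_segments(), seed=0)
    assert pop.n_respondents == 718
    assert np.bincount(pop.segment_labels).tolist() == [125, 188, 115, 86, 204]
    assert pop.beta.shape == (718, 9)


def test_population_is_deterministic_given_seed():
    a = ck.make_population(ck.default_segments(), seed=5)
    b = ck.make_population(ck.default_segments(), seed=5)
    c = ck.make_population(ck.default_segments(), seed=6)
    assert np.array_equal(a.beta, b.beta)
    assert not np.array_equal(a.beta, c.beta)


def test_zero_spread_collapses_to_segment_mean():
    seg = SegmentDefinition(
        "flat", 10, {"a": (2.0, -2.0)}, none_utility=-5.0, spread=0.0
    )
    pop = ck.make_population([seg], logit_scale=1.0, seed=0, space=one_attr_space())
    assert np.allclose(pop.beta, pop.beta[0])
    assert pop.beta[0, 0] == pytest.approx(2.0)
    assert pop.beta[0, 1] == pytest.approx(-5.0)


def test_between_segment_difference_recovered_monte_carlo():
    """Two segments +/- 2 on a binary attribute: empirical gap ~ 4."""
    segs = [
        SegmentDefinition("up", 500, {"a": (2.0, -2.0)}, 0.0, spread=0.1),
        SegmentDefinition("down", 500, {"a": (-2.0, 2.0)}, 0.0, spread=0.1),
    ]
    pop = ck.make_population(segs, logit_scale=1.0, seed=1, space=one_attr_space())
    gap = pop.beta[:500, 0].mean() - pop.beta[500:, 0].mean()
    se = 0.1 * np.sqrt(2 / 500)
    assert abs(gap - 4.0) < 3 * se


def test_nonpositive_logit_scale_rejected():
    with pytest.raises(ck.ConfigurationError):
        ck.make_population(ck.default_segments(), logit_scale=0.0, seed=0)


def test_uniform_choice_under_flat_utilities():
    seg = SegmentDefinition("flat", 9000, {"a": (0.0, 0.0)}, 0.0, spread=0.0)
    pop = ck.make_population([seg], logit_scale=1.0, seed=2, space=one_attr_space())
    ds = ck.simulate_choices(pop, one_task_design(), seed=3)
    freqs = ds.tasks["chosen"].value_counts(normalize=True)
    for alt in (0.0, 1.0, float(NONE_CHOICE)):
        assert freqs[alt] == pytest.approx(1 / 3, abs=0.02)


def test_choice_frequency_matches_closed_form_logit():
    """Utilities (+1, -1), None at -50: P(first) = e^2/(e^2+1) ~ 0.881."""
    seg = SegmentDefinition("sure", 10_000, {"a": (1.0, -1.0)}, -50.0, spread=0.0)
    pop = ck.make_population([seg], logit_scale=1.0, seed=4, space=one_attr_space())
    ds = ck.simulate_choices(pop, one_task_design(), seed=5)
    p_hat = (ds.tasks["chosen"] == 0).mean()
    p_true = np.exp(2) / (np.exp(2) + 1)
    assert p_hat == pytest.approx(p_true, abs=3 * np.sqrt(p_true * (1 - p_true) / 10_000))


def test_injectable_segment_prefers_injectable_over_daily_oral(space, small_design):
    """Dominant injectable segment chooses injectable concepts over daily-oral."""
    seg1 = ck.default_segments()[0]
    pop = ck.make_population([seg1], seed=6)
    ds = ck.simulate_choices(pop, small_design, seed=7)
    shown = ds.concept_levels()  # (n_tasks, 2, 5)
    chosen = ds.tasks["chosen"].to_numpy()
    # tasks pairing an injectable concept (level 0) against a daily-oral one (level 2)
    mask = ((shown[:, 0, 0] == 0) & (shown[:, 1, 0] == 2)) | (
        (shown[:, 0, 0] == 2) & (shown[:, 1, 0] == 0)
    )
    inj_concept = np.where(shown[mask, 0, 0] == 0, 0, 1)
    inj_rate = (chosen[mask] == inj_concept).mean()
    oral_rate = (chosen[mask] == 1 - inj_concept).mean()
    assert inj_rate > oral_rate


def test_inject_artifacts_identity_when_all_zero(space, small_design):
    pop = ck.make_population(ck.default_segments()[:1], seed=8)
    ds = ck.simulate_choices(pop, small_design, seed=9)
    out, counts = ck.inject_artifacts(ds, ck.ArtifactConfig(), seed=10)
    assert sum(counts.values()) == 0
    assert out.tasks.equals(ds.tasks)
    assert out.respondents.equals(ds.respondents)


def test_straightliner_injection_count_exact(space, small_design):
    seg = SegmentDefinition("m", 100, ck.default_segments()[0].level_utilities, -300.0)
    pop = ck.make_population([seg], seed=11)
    ds = ck.simulate_choices(pop, small_design, seed=12)
    out, counts = ck.inject_artifacts(
        ds, ck.ArtifactConfig(straightliner_fraction=0.1), seed=13
    )
    assert counts["straightliner"] == 10
    flat = out.tasks.groupby("respondent_id")["chosen"].nunique()
    assert int((flat == 1).sum()) == 10


def test_artifact_fractions_validated():
    with pytest.raises(ck.ConfigurationError):
        ck.ArtifactConfig(speeder_fraction=0.7, duplicate_fraction=0.6)
    with pytest.raises(ck.ConfigurationError):
        ck.ArtifactConfig(speeder_fraction=-0.1)


def test_dataset_csv_round_trip(space, small_design, tmp_path):
    pop = ck.make_population(ck.default_segments()[:2], seed=14)
    ds = ck.simulate_choices(pop, small_design, seed=15)
    ds, _ = ck.inject_artifacts(
        ds, ck.ArtifactConfig(incomplete_fraction=0.05), seed=16
    )
    ds = ck.add_screenouts(ds, 7, seed=17)
    path = tmp_path / "choices.csv"
    ds.to_csv(path)
    back = ck.ChoiceDataset.from_csv(path)
    assert back.attr_names == ds.attr_names
    assert len(back.respondents) == len(ds.respondents)
    assert back.tasks["chosen"].equals(ds.tasks["chosen"])
    assert back.concept_levels().tolist() == ds.concept_levels().tolist()
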