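"""Share-of-preference simulators: scenarios, limits, symmetry, sweeps."""

import numpy as np
import pytest

import cbckit as ck
from cbckit.attributes import (
    COST,
    COST_HIGH,
    COST_LOW,
    DOSING,
    DISPENSING,
    INJECTABLE,
    MAIL,
    ONE_WEEK,
    PICKUP,
)


@pytest.fixture(scope="module")
def estimate(space, small_design):
    """Zero-centered estimate built directly from generating coefficients."""
    pop = ck.make_population(ck.default_segments(), seed=50)
    return ck.zero_center(pop.beta, ck.CodingMap(space)), pop


def test_default_scenarios_match_reference_program_definitions(space, prohibitions):
    scenarios = ck.build_scenarios(space, prohibitions)
    names = [s.name for s in scenarios]
    assert names == [
        "Injectable PrEP best case",
        "Injectable PrEP worst case",
        "Oral daily PrEP best case",
        "Oral daily PrEP worst case",
        "On-demand PrEP best case",
        "On-demand PrEP worst case",
    ]
    inj_best = scenarios[0]
    assert inj_best.levels[COST] == COST_LOW
    assert inj_best.levels[DISPENSING] == PICKUP
    assert inj_best.levels["visit_burden"] == ONE_WEEK
    inj_worst = scenarios[1]
    assert inj_worst.levels[COST] == COST_HIGH


def test_prohibited_scenario_rejected(space, prohibitions):
    bad = ck.Scenario(
        "mailed injectable",
        {
            DOSING: INJECTABLE,
            COST: COST_LOW,
            "clinician_interaction": "Online",
            DISPENSING: MAIL,
            "visit_burden": "Same day",
        },
    )
    with pytest.raises(ck.ConfigurationError, match="prohibition"):
        bad.validate(space, prohibitions)


def test_scenario_yaml_round_trip(space, prohibitions, tmp_path):
    scenarios = ck.build_scenarios(space, prohibitions)
    path = tmp_path / "scenarios.yaml"
    ck.scenarios_to_yaml(scenarios, path)
    back = ck.build_scenarios(space, prohibitions, source=path)
    assert back == scenarios


def test_dominant_program_gets_full_share_without_error(space, estimate):
    est, pop = estimate
    scenarios = ck.build_scenarios(space)
    # segment 5 (index 4) almost always prefers any program to opting out
    g5 = ck.UtilityEstimate(
        raw=est.raw[pop.segment_labels == 4],
        levels_zc=est.levels_zc[pop.segment_labels == 4],
        none_zc=est.none_zc[pop.segment_labels == 4],
        importance=est.importance[pop.segment_labels == 4],
        multiplier=est.multiplier[pop.segment_labels == 4],
        coding=est.coding,
        respondent_ids=est.respondent_ids[pop.segment_labels == 4],
    )
    rep = ck.simulate_shares(g5, [scenarios[4]], config=ck.SimConfig(model="first_choice"))
    assert rep.shares.iloc[0]["Total"] == pytest.approx(100.0)


def test_program_plus_none_share_is_exactly_100(space, estimate):
    est, pop = estimate
    scenarios = ck.build_scenarios(space)
    rep = ck.simulate_shares(
        est, scenarios, pop.segment_labels, ck.SimConfig(model="rfc", n_draws=50, seed=1)
    )
    total = rep.shares + rep.none_shares()
    np.testing.assert_allclose(total.to_numpy(), 100.0, atol=1e-12)
    assert ((rep.shares >= 0) & (rep.shares <= 100)).all().all()


def test_rfc_converges_to_first_choice_as_errors_vanish(space, estimate):
    est, _ = estimate
    scenarios = ck.build_scenarios(space)[:2]
    fc = ck.simulate_shares(est, scenarios, config=ck.SimConfig(model="first_choice"))
    limit = ck.simulate_shares(
        est,
        scenarios,
        config=ck.SimConfig(
            model="rfc",
            n_draws=10_000,
            attribute_error_scale=1e-6,
            product_error_scale=1e-6,
            seed=2,
        ),
    )
    diff = np.abs(fc.shares.to_numpy() - limit.shares.to_numpy()).max()
    assert diff < 0.5


def test_identical_alternatives_split_fifty_fifty(space):
    """A program whose utility equals the opt-out's is a coin flip under RFC."""
    cm = ck.CodingMap(space)
    raw = np.zeros((40, cm.n_params))  # all utilities equal (and zero)
    with pytest.warns(UserWarning, match="all-flat"):
        est = ck.zero_center(raw, cm)
    scen = ck.build_scenarios(space)[:1]
    fc = ck.simulate_shares(est, scen, config=ck.SimConfig(model="first_choice"))
    assert fc.shares.iloc[0]["Total"] == pytest.approx(50.0)  # exact tie rule
    rfc = ck.simulate_shares(
        est,
        scen,
        config=ck.SimConfig(
            model="rfc", n_draws=2000, attribute_error_scale=0.0, seed=3
        ),
    )
    assert rfc.shares.iloc[0]["Total"] == pytest.approx(50.0, abs=2.5)


def test_logit_and_first_choice_agree_for_large_margins(space, estimate):
    """With every raw margin beyond 20, the logistic share is 0/1 in effect."""
    est, pop = estimate
    cm = est.coding
    raw = est.raw.copy()
    raw[:, cm.none_col] = -40.0  # |u - u_none| > 20 for every respondent
    decisive = ck.zero_center(raw, cm)
    scen = ck.build_scenarios(space)[:3]
    fc = ck.simulate_shares(decisive, scen, config=ck.SimConfig(model="first_choice"))
    lg = ck.simulate_shares(decisive, scen, config=ck.SimConfig(model="logit"))
    x = cm.encode_concept(scen[0].concept(space).levels)
    assert np.all(np.abs(raw @ x - raw[:, cm.none_col]) > 20)
    assert np.abs(fc.shares.to_numpy() - lg.shares.to_numpy()).max() < 0.01


def test_monte_carlo_error_shrinks_with_draw_count(space, estimate):
    est, _ = estimate
    scen = ck.build_scenarios(space)[:1]

    def spread(n_draws, seeds):
        vals = [
            ck.simulate_shares(
                est, scen, config=ck.SimConfig(model="rfc", n_draws=n_draws, seed=s)
            ).shares.iloc[0]["Total"]
            for s in seeds
        ]
        return np.std(vals)

    s_small = spread(8, range(12))
    s_large = spread(128, range(12, 24))
    # fourfold draw increase should shrink the error roughly fourfold (sqrt(16))
    assert s_large < s_small / 2


def test_sensitivity_sweep_structure_and_cost_monotonicity(space, estimate):
    est, _ = estimate
    base = ck.build_scenarios(space)[3]  # oral worst case
    sweep = ck.sensitivity_table(est, base, COST, ck.SimConfig(model="logit"))
    assert len(sweep) == 2
    assert not sweep["prohibited"].any()
    # the cohort's cost utilities favor the cheap level in every segment
    share = dict(zip(sweep["level"], sweep["share"]))
    assert share[COST_LOW] >= share[COST_HIGH]
    # swapping dosing into the oral worst case keeps the other levels fixed
    dosing_sweep = ck.sensitivity_table(est, base, DOSING, ck.SimConfig(model="logit"))
    assert len(dosing_sweep) == 3
    assert not dosing_sweep["share"].isna().any()


def test_mailed_injectable_sweep_cell_flagged_as_prohibited(space, estimate):
    est, _ = estimate
    inj_best = ck.build_scenarios(space)[0]
    sweep = ck.sensitivity_table(est, inj_best, DISPENSING, ck.SimConfig(model="logit"))
    flagged = dict(zip(sweep["level"], sweep["prohibited"]))
    assert flagged[MAIL] is True or flagged[MAIL] == True  # noqa: E712
    assert np.isnan(sweep.loc[sweep["level"] == MAIL, "share"]).all()
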