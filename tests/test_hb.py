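"""Hierarchical Bayes estimation: transforms, sampler behavior, tiny-grid oracle."""

import numpy as np
import pytest

import cbckit as ck
from cbckit.attributes import Attribute, AttributeSpace
from cbckit.mnl import build_arrays


def test_zero_centering_matches_arithmetic_oracle():
    """One attribute with utilities (3, -1, -2): range 5 -> multiplier 20."""
    space = AttributeSpace((Attribute("a", ("x", "y", "z")),))
    cm = ck.CodingMap(space)
    beta = cm.contract(np.array([[3.0, -1.0, -2.0]]), none=np.array([5.0]))
    est = ck.zero_center(beta, cm)
    assert est.multiplier[0] == pytest.approx(20.0)
    assert est.levels_zc[0].tolist() == pytest.approx([60.0, -20.0, -40.0])
    assert est.none_zc[0] == pytest.approx(100.0)
    assert est.importance[0, 0] == pytest.approx(100.0)


def test_flat_respondent_keeps_unit_multiplier_with_warning(space):
    cm = ck.CodingMap(space)
    beta = np.zeros((1, cm.n_params))
    with pytest.warns(UserWarning, match="all-flat"):
        est = ck.zero_center(beta, cm)
    assert est.multiplier[0] == 1.0
    assert np.all(est.levels_zc == 0.0)
    assert est.importance[0].tolist() == pytest.approx([20.0] * 5)


def test_relative_importance_matches_hand_ratios():
    """Ranges (54.1, 188, 51.8, 34.5, 28.9) -> RIS (15.1, 52.6, 14.5, 9.7, 8.1)."""
    space = AttributeSpace(
        tuple(Attribute(f"a{i}", ("hi", "lo")) for i in range(5))
    )
    cm = ck.CodingMap(space)
    ranges = np.array([54.1, 188.0, 51.8, 34.5, 28.9])
    levels = np.column_stack(
        [v for r in ranges for v in (np.array([r / 2]), np.array([-r / 2]))]
    )
    beta = cm.contract(levels, none=np.zeros(1))
    est = ck.zero_center(beta, cm)
    assert est.importance[0].sum() == pytest.approx(100.0)
    assert np.round(est.importance[0], 1).tolist() == [15.1, 52.6, 14.5, 9.7, 8.1]


def test_group_importance_and_utility_tables_have_expected_shape(space, small_design):
    pop = ck.make_population(ck.default_segments()[:2], seed=30)
    ds = ck.simulate_choices(pop, small_design, seed=31)
    cm = ck.CodingMap(space)
    est = ck.zero_center(pop.beta, cm)  # tables only need a coefficient matrix
    ris = ck.importance_table(est, pop.segment_labels)
    assert list(ris.index) == space.names
    assert ris.shape == (5, 3)  # Total + 2 groups
    np.testing.assert_allclose(ris.sum(axis=0), 100.0, atol=1e-9)
    utab = ck.utilities_table(est, pop.segment_labels)
    assert utab.shape == (14, 3)  # 13 levels + None row
    assert utab.index[-1] == "None"
    # group means of zero-centered utilities stay zero-centered per attribute
    pos = 0
    for attr in space:
        block = utab.iloc[pos : pos + attr.n_levels]
        np.testing.assert_allclose(block.sum(axis=0), 0.0, atol=1e-9)
        pos += attr.n_levels


def test_hb_chain_is_deterministic_given_seed(space, small_design):
    pop = ck.make_population(ck.default_segments()[:1], seed=32)
    ds = ck.simulate_choices(pop, small_design, seed=33)
    arr = build_arrays(ds, ck.CodingMap(space))
    cfg = ck.HBConfig(n_burn=50, n_draws=50, thin=5, seed=7)
    d1 = ck.fit_hb(arr, cfg)
    d2 = ck.fit_hb(arr, cfg)
    assert np.array_equal(d1.mu, d2.mu)
    assert np.array_equal(d1.beta, d2.beta)


def test_always_none_respondent_shifts_none_constant_positive(make_manual_arrays):
    """Flat data that always opts out pulls the None constant above its prior mean."""
    space = AttributeSpace((Attribute("a", ("x", "y")),))
    cm = ck.CodingMap(space)
    X = np.zeros((8, 3, cm.n_params))
    X[:, 0] = cm.encode_concept([0])
    X[:, 1] = cm.encode_concept([1])
    X[:, 2] = cm.encode_none()
    arrays = make_manual_arrays(X, chosen=[2] * 8)
    draws = ck.fit_hb(arrays, ck.HBConfig(n_burn=400, n_draws=400, thin=2, seed=1))
    none_mean = draws.beta_mean[0, cm.none_col]
    assert none_mean > 0.5


def test_posterior_mean_matches_brute_force_grid_oracle(make_manual_arrays):
    """2 respondents, 1 coefficient: sampler vs direct grid integration.

    The inverse-Wishart scale is integrated out analytically
    (sigma^2 ~ InvGamma(df/2, scale/2)), leaving a 3-dimensional posterior
    over (beta_1, beta_2, mu) evaluated on a dense grid.
    """
    space = AttributeSpace((Attribute("a", ("x", "y")),))
    cm = ck.CodingMap(space, include_none=False)
    x0, x1 = cm.encode_concept([0]), cm.encode_concept([1])
    # respondent 0: chooses level x four times in five; respondent 1: one in five
    X = np.tile(np.stack([x0, x1])[None], (10, 1, 1))
    chosen = [0, 0, 0, 0, 1, 1, 1, 1, 1, 0]
    resp = [0] * 5 + [1] * 5
    arrays = make_manual_arrays(X, chosen, resp)

    cfg = ck.HBConfig(
        n_burn=3000, n_draws=12000, thin=3, seed=3, prior_df_extra=5, prior_scale=1.0
    )
    draws = ck.fit_hb(arrays, cfg)

    # --- brute-force oracle -------------------------------------------------
    g = np.linspace(-6.0, 6.0, 161)
    b1, b2, mu = np.meshgrid(g, g, g, indexing="ij", sparse=True)

    def loglik(beta, n_hi, n_lo):
        # each task: margin (x0 - x1) . beta = 2 beta
        return n_hi * (-np.log1p(np.exp(-2 * beta))) + n_lo * (
            -np.log1p(np.exp(2 * beta))
        )

    df0 = 1 + cfg.prior_df_extra  # p + extra
    a_post = df0 / 2 + 1.0  # two respondents
    quad = (b1 - mu) ** 2 + (b2 - mu) ** 2
    log_post = (
        loglik(b1, 4, 1)
        + loglik(b2, 1, 4)
        - (a_post) * np.log(cfg.prior_scale / 2 + quad / 2)
        - mu**2 / (2 * cfg.prior_mean_var)
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    e_b1 = float((w * b1).sum())
    e_b2 = float((w * b2).sum())
    e_mu = float((w * mu).sum())

    assert draws.beta_mean[0, 0] == pytest.approx(e_b1, abs=0.12)
    assert draws.beta_mean[1, 0] == pytest.approx(e_b2, abs=0.12)
    assert draws.mu_mean[0] == pytest.approx(e_mu, abs=0.12)


def test_population_mean_recovery_on_two_separated_segments(space, small_design):
    """Short-chain recovery smoke test on a well-separated two-segment cohort."""
    from cbckit.cohort import SegmentDefinition

    segs = [
        SegmentDefinition("a", 60, ck.default_segments()[0].level_utilities, -300.0),
        SegmentDefinition("b", 60, ck.default_segments()[4].level_utilities, -300.0),
    ]
    pop = ck.make_population(segs, seed=34)
    ds = ck.simulate_choices(pop, small_design, seed=35)
    arr = build_arrays(ds, ck.CodingMap(space))
    draws = ck.fit_hb(arr, ck.HBConfig(n_burn=600, n_draws=600, thin=3, seed=36))
    corr = np.corrcoef(draws.mu_mean, pop.population_mean())[0, 1]
    assert corr > 0.9
    assert np.corrcoef(draws.beta_mean.ravel(), pop.beta.ravel())[0, 1] > 0.8
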