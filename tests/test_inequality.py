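"""Fractional ranks and the Wagstaff concentration index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcci import (
    SyntheticConfig,
    generate_survey,
    community_prevalence,
    fit_one_factor,
    score_communities,
    select_k,
    fractional_rank,
    wagstaff_ci,
    risk_gradient_table,
)


def test_fractional_rank_hand_cases():
    g = np.array(["a", "a", "b", "b"])
    w = np.ones(4)
    r = fractional_rank(g, w, ["a", "b"])
    np.testing.assert_allclose(r.rank_per_group, [0.25, 0.75])

    r1 = fractional_rank(np.array(["a"] * 5), np.ones(5), ["a"])
    np.testing.assert_allclose(r1.rank, 0.5)

    g2 = np.array(["a", "b"])
    r2 = fractional_rank(g2, np.array([0.2, 0.8]), ["a", "b"])
    np.testing.assert_allclose(r2.rank_per_group, [0.1, 0.6])


def test_weighted_mean_rank_is_half(rng):
    g = rng.choice(list("abcd"), 200)
    w = rng.gamma(2, 1, 200)
    r = fractional_rank(g, w, list("abcd"))
    assert np.dot(w, r.rank) / w.sum() == pytest.approx(0.5, abs=1e-10)
    assert np.all(np.diff(r.rank_per_group) > 0)


def test_rank_errors():
    with pytest.raises(ValueError, match="outside"):
        fractional_rank(np.array(["a", "z"]), np.ones(2), ["a", "b"])
    with pytest.raises(ValueError, match="empty"):
        fractional_rank(np.array(["a", "a"]), np.ones(2), ["a", "b"])
    with pytest.raises(ValueError, match="positive"):
        fractional_rank(np.array(["a", "b"]), np.array([1.0, 0.0]), ["a", "b"])


def _two_group_data(p_a, p_b, n=1000):
    y = np.concatenate([np.repeat([1, 0], [int(p_a * n), n - int(p_a * n)]),
                        np.repeat([1, 0], [int(p_b * n), n - int(p_b * n)])])
    g = np.repeat(["a", "b"], n)
    return y.astype(float), g, np.ones(2 * n)


def test_wagstaff_hand_case():
    y, g, w = _two_group_data(0.1, 0.3)
    r = fractional_rank(g, w, ["a", "b"])
    res = wagstaff_ci(y, r, w)
    assert res.mu == pytest.approx(0.2)
    assert res.raw_ci == pytest.approx(0.25, abs=1e-12)
    assert res.corrected_ci == pytest.approx(0.3125, abs=1e-12)


def test_no_inequality_gives_zero():
    y, g, w = _two_group_data(0.2, 0.2)
    r = fractional_rank(g, w, ["a", "b"])
    assert wagstaff_ci(y, r, w).raw_ci == pytest.approx(0.0, abs=1e-12)


def test_reversing_group_order_negates_index():
    y, g, w = _two_group_data(0.1, 0.3)
    fwd = wagstaff_ci(y, fractional_rank(g, w, ["a", "b"]), w)
    rev = wagstaff_ci(y, fractional_rank(g, w, ["b", "a"]), w)
    assert fwd.raw_ci == pytest.approx(-rev.raw_ci, abs=1e-12)
    assert fwd.corrected_ci == pytest.approx(-rev.corrected_ci, abs=1e-12)


def test_degenerate_mean_is_an_error():
    y = np.ones(4)
    g = np.array(["a", "a", "b", "b"])
    r = fractional_rank(g, np.ones(4), ["a", "b"])
    with pytest.raises(ValueError, match="outside"):
        wagstaff_ci(y, r, np.ones(4))


@given(seed=st.integers(0, 500))
@settings(max_examples=40, deadline=None)
def test_matches_grouped_formula_oracle(seed):
    """Individual-level weighted covariance equals the grouped-share formula."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    n_groups = int(rng.integers(2, 6))
    order = [f"g{i}" for i in range(n_groups)]
    g = rng.choice(order, n)
    for lab in order:  # ensure non-empty groups
        g[rng.integers(0, n)] = lab
    w = rng.gamma(2.0, 1.0, n)
    y = (rng.random(n) < 0.4).astype(float)
    if y.mean() in (0.0, 1.0):
        y[0], y[1] = 1.0, 0.0
    r = fractional_rank(g, w, order)
    res = wagstaff_ci(y, r, w)

    # oracle: CI = (2/mu) * sum_g s_g (p_g - mu)(R_g - 0.5) over groups
    mu = np.dot(w, y) / w.sum()
    acc = 0.0
    for i, lab in enumerate(order):
        m = g == lab
        s_g = w[m].sum() / w.sum()
        p_g = np.average(y[m], weights=w[m])
        acc += s_g * (p_g - mu) * (r.rank_per_group[i] - 0.5)
    assert res.raw_ci == pytest.approx(2.0 / mu * acc, abs=1e-12)
    assert -1 - 1e-12 <= res.corrected_ci <= 1 + 1e-12

    scaled = wagstaff_ci(y, fractional_rank(g, 7.5 * w, order), 7.5 * w)
    assert scaled.raw_ci == pytest.approx(res.raw_ci, abs=1e-12)


def _gccs_for(df):
    cp = community_prevalence(df)
    model = fit_one_factor(cp)
    s = score_communities(model, cp)
    return select_k(s.score, s.community_id)


def test_context_driven_outcome_has_positive_gradient_and_ci():
    df = generate_survey(SyntheticConfig(n_communities=40, n_per_community=250, seed=5))
    gccs = _gccs_for(df)
    table, res = risk_gradient_table(df, gccs, ["multiparity"])
    assert res["multiparity"].corrected_ci > 0
    # complementary outcome concentrates on the other end: sign flips
    df2 = df.copy()
    df2["not_multiparity"] = 1 - df2["multiparity"]
    _, res2 = risk_gradient_table(df2, gccs, ["not_multiparity"])
    assert res2["not_multiparity"].corrected_ci < 0


def test_outcome_independent_of_context_has_near_zero_ci(rng):
    df = generate_survey(SyntheticConfig(n_communities=40, n_per_community=250, seed=6))
    gccs = _gccs_for(df)
    df = df.copy()
    df["coin"] = (rng.random(len(df)) < 0.3).astype(int)
    _, res = risk_gradient_table(df, gccs, ["coin"])
    assert abs(res["coin"].corrected_ci) < 0.03


def test_ci_magnitude_increases_with_context_effect():
    cis = []
    for effect in (0.0, 0.4, 1.0):
        df = generate_survey(
            SyntheticConfig(
                n_communities=40,
                n_per_community=300,
                outcome_context_effect=effect,
                outcome_residual_community_sd=0.1,
                seed=9,
            )
        )
        gccs = _gccs_for(df)
        _, res = risk_gradient_table(df, gccs, ["multiparity"])
        cis.append(abs(res["multiparity"].corrected_ci))
    assert cis[0] < cis[1] < cis[2]


def test_non_binary_outcome_is_an_error(default_survey, default_gccs):
    df = default_survey.copy()
    df["bad"] = df["age"]
    with pytest.raises(ValueError, match="binary"):
        risk_gradient_table(df, default_gccs, ["bad"])
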