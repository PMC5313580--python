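import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import oracle
from riskselect import (
    MarketConfig,
    group_compensation,
    identify_switchers,
    naive_insurer_estimate,
    overrepresentation_index,
    predict_and_residualize,
    significance_test,
    simulate_market,
    switcher_estimates,
)


def _residual_frame(actual, predicted, insurer=None, year=2009):
    n = len(actual)
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "year": year,
            "insurer_id": insurer if insurer is not None else np.ones(n, int),
            "actual": actual,
            "predicted": predicted,
            "residual": actual - predicted,
            "overcompensation": predicted - actual,
        }
    )


# ------------------------------------------------------------------ #
# significance test


def test_symmetric_two_point_sample_gives_p_one():
    res = significance_test(np.array([-1.0, 1.0]))
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_zero_variance_sample_is_degenerate():
    res = significance_test(np.zeros(5))
    assert res.degenerate and res.p_value == 1.0


def test_too_small_sample_raises():
    with pytest.raises(ValueError):
        significance_test(np.array([1.0]))


def test_large_sample_normal_approximation_is_continuous():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 10_500)
    exact = significance_test(x[:10_000])
    approx = significance_test(x)
    assert 0 < approx.p_value < 1
    assert abs(exact.p_value - approx.p_value) < 0.2


def test_type_i_error_calibrated_on_heavy_tailed_null():
    """Two-sided size stays near nominal for skewed (gamma) nulls."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 800
    for _ in range(n_rep):
        x = rng.standard_gamma(0.5, 2_000) - 0.5
        if significance_test(x).p_value < 0.05:
            rejections += 1
    assert 0.03 < rejections / n_rep < 0.07


# ------------------------------------------------------------------ #
# group compensation


def test_group_compensation_arithmetic():
    res = _residual_frame([1000.0] * 4, [850.0] * 4)
    row = group_compensation(res, np.ones(4, bool), overall_mean=1570.0)
    assert row.mean_overcompensation == -150.0
    assert row.predictive_ratio == 0.85
    assert row.population_share == 1.0


def test_reduction_versus_no_equalization():
    # group mean actual 2000, overall mean 1000 -> no-equalization
    # overcompensation -1000; model overcompensation -250 -> 75% reduction
    res = _residual_frame([2000.0] * 3, [1750.0] * 3)
    row = group_compensation(res, np.ones(3, bool), overall_mean=1000.0)
    assert row.mean_overcompensation == -250.0
    assert np.isclose(row.reduction_vs_no_equalization, 0.75)


def test_published_style_pair_is_internally_consistent():
    """An undercompensation of -670 on mean actual expenses 4466.67 prints
    as predictive ratio 0.85 — the two columns are one identity."""
    res = _residual_frame([4466.67, 4466.67], [3796.67, 3796.67])
    row = group_compensation(res, np.ones(2, bool), overall_mean=1570.0)
    assert np.isclose(row.mean_overcompensation, -670.0)
    assert round(row.predictive_ratio, 2) == 0.85


@given(
    st.lists(
        st.tuples(st.floats(1.0, 5e3), st.floats(-5e3, 5e3)),
        min_size=2,
        max_size=30,
    )
)
def test_overcompensation_predictive_ratio_identity(pairs):
    actual = [a for a, _ in pairs]
    predicted = [p for _, p in pairs]
    res = _residual_frame(actual, predicted)
    row = group_compensation(res, np.ones(len(pairs), bool), overall_mean=1.0)
    lhs = row.mean_overcompensation
    rhs = row.mean_actual * (row.predictive_ratio - 1.0)
    assert np.isclose(lhs, rhs, rtol=1e-9, atol=1e-9)


def test_empty_group_raises():
    res = _residual_frame([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="empty"):
        group_compensation(res, np.zeros(2, bool), overall_mean=1.0)


# ------------------------------------------------------------------ #
# overrepresentation


def test_overrepresentation_trivial_ratios():
    panel = pd.DataFrame(
        {
            "person_id": np.arange(10),
            "insurer_id": [1] * 5 + [2] * 5,
        }
    )
    member = np.array([True] * 2 + [False] * 3 + [True] * 2 + [False] * 3)
    res = overrepresentation_index(panel, 1, member)
    assert res.index == 1.0
    member2 = np.array([True, True, True, False, False] + [True, False, False, False, False])
    res2 = overrepresentation_index(panel, 1, member2)
    assert np.isclose(res2.index, 0.6 / 0.4)


def test_overrepresentation_null_market_indices_near_one():
    rng = np.random.default_rng(21)
    n = 100_000
    panel = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "insurer_id": rng.integers(1, 26, n),
        }
    )
    member = rng.random(n) < 0.2
    rejections = 0
    for j in range(1, 26):
        res = overrepresentation_index(panel, j, member)
        assert 0.85 < res.index < 1.15
        rejections += res.significant_05
    assert rejections <= 5  # ~5% of 25 binomial tests under the null


# ------------------------------------------------------------------ #
# naive estimate and switchers


def test_naive_estimate_hand_toy():
    res = _residual_frame(
        actual=[10.0, -10.0, 30.0, 10.0],
        predicted=[0.0, 0.0, 0.0, 0.0],
        insurer=np.array([1, 1, 2, 2]),
    )
    table = naive_insurer_estimate(res)
    assert table.loc[1, "mean_overcompensation"] == 0.0
    assert table.loc[2, "mean_overcompensation"] == -20.0


def test_identify_switchers_classification(toy_panel):
    sw = identify_switchers(toy_panel).set_index("person_id")
    assert bool(sw.loc[1, "switched"]) and sw.loc[1, "origin"] == 1
    assert sw.loc[1, "destination"] == 2
    assert not bool(sw.loc[2, "switched"])
    assert sw.attrs["n_single_year"] == 0


def test_single_year_persons_excluded_and_tallied(toy_panel):
    extra = pd.DataFrame(
        [[7, 2008, 1, 123.0]], columns=["person_id", "year", "insurer_id", "expenses"]
    )
    panel = pd.concat([toy_panel, extra], ignore_index=True)
    sw = identify_switchers(panel)
    assert 7 not in set(sw["person_id"])
    assert sw.attrs["n_single_year"] == 1


def test_duplicate_person_year_is_data_error(toy_panel):
    panel = pd.concat([toy_panel, toy_panel.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        identify_switchers(panel)


def test_switcher_estimates_match_hand_enumeration(toy_panel, flat_model):
    """Six persons, predictions fixed at 800: inflow/outflow means are
    checkable by hand (and by the brute-force oracle)."""
    residuals = {
        y: predict_and_residualize(toy_panel, flat_model, y) for y in (2008, 2009)
    }
    table = switcher_estimates(toy_panel, residuals, order="insurer_id")
    t = table.set_index("insurer_id")
    # inflow to 2: persons 1 and 5, overcompensation 800-1000 and 800-300
    assert t.loc[2, "n_inflow"] == 2
    assert t.loc[2, "inflow_overcompensation"] == 150.0
    # outflow from 1: persons 1 and 5 in 2009: 800-500 and 800-400
    assert t.loc[1, "outflow_overcompensation"] == 350.0
    # single-switcher cells are unavailable
    assert t.loc[1, "n_inflow"] == 1 and not t.loc[1, "inflow_available"]
    assert t.loc[2, "n_outflow"] == 1 and not t.loc[2, "outflow_available"]
    # ordering key: non-switcher mean year-t residuals (2: 200, 1: -200)
    ordered = switcher_estimates(toy_panel, residuals)
    assert list(ordered["insurer_id"]) == [2, 1]
    # against the independent enumeration
    lookup = oracle.residual_lookup(
        pd.concat([residuals[2008], residuals[2009]], ignore_index=True)
    )
    enum = oracle.oracle_switchers(toy_panel, lookup)
    assert enum[2]["inflow"] == t.loc[2, "inflow_overcompensation"]
    assert enum[1]["outflow"] == t.loc[1, "outflow_overcompensation"]


def test_all_estimators_match_bruteforce_on_random_small_panel(flat_model):
    """On a 50-person simulated market every estimator must agree with
    plain-loop enumeration bit-exactly."""
    cfg = MarketConfig(
        n_persons=50, n_insurers=3, seed=33, switch_rate=0.35
    )
    panel, _ = simulate_market(cfg)
    model = flat_model
    residuals = {
        y: predict_and_residualize(panel, model, y) for y in cfg.years
    }
    # naive
    table = naive_insurer_estimate(residuals[2009])
    for j, val in oracle.oracle_naive(residuals[2009]).items():
        assert table.loc[j, "mean_overcompensation"] == val
    # group compensation
    rows = residuals[2009]
    member = (rows["actual"] > rows["actual"].median()).to_numpy()
    row = group_compensation(rows, member, overall_mean=model.overall_mean)
    n, over, pr, mean_actual = oracle.oracle_group(rows, member)
    assert (row.n_members, row.mean_overcompensation) == (n, over)
    assert row.predictive_ratio == pr
    # overrepresentation
    panel9 = panel[panel["year"] == 2009].reset_index(drop=True)
    member9 = (panel9["expenses"] == 0).to_numpy()
    res = overrepresentation_index(panel9, 2, member9)
    idx, ins_share, pop_share = oracle.oracle_overrepresentation(panel9, 2, member9)
    assert (res.index, res.insurer_share, res.population_share) == (
        idx,
        ins_share,
        pop_share,
    )
    # switchers
    table = switcher_estimates(panel, residuals, order="insurer_id").set_index(
        "insurer_id"
    )
    lookup = oracle.residual_lookup(
        pd.concat([residuals[2008], residuals[2009]], ignore_index=True)
    )
    enum = oracle.oracle_switchers(panel, lookup)
    for j, rec in enum.items():
        assert table.loc[j, "n_inflow"] == rec["n_inflow"]
        assert table.loc[j, "n_outflow"] == rec["n_outflow"]
        if rec["inflow"] is not None:
            assert table.loc[j, "inflow_overcompensation"] == rec["inflow"]
        else:
            assert not table.loc[j, "inflow_available"]
        if rec["outflow"] is not None:
            assert table.loc[j, "outflow_overcompensation"] == rec["outflow"]
        else:
            assert not table.loc[j, "outflow_available"]
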