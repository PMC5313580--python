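import numpy as np
import pandas as pd
import pytest

from riskselect import (
    MarketConfig,
    UnpricedSpec,
    assign_and_switch,
    calibrate_inflow_selection,
    expected_inflow_unpriced,
    generate_population,
    panel_ground_truth,
    realize_expenses,
    simulate_market,
)


def _binomial_99_interval(p, n):
    half = 2.576 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def test_empty_population_is_degenerate_but_valid():
    cfg = MarketConfig(n_persons=0, seed=1)
    pop = generate_population(cfg)
    assert len(pop) == 0
    assignments, truth = assign_and_switch(pop, cfg)
    assert len(assignments) == 0
    assert truth.inflow_n[1] == 0


def test_population_shares_match_spec():
    cfg = MarketConfig(n_persons=100_000, seed=5)
    pop = generate_population(cfg)
    lo, hi = _binomial_99_interval(0.315, len(pop))
    assert lo < (pop["chronic"] == "1").mean() < hi


def test_same_seed_same_panel():
    cfg = MarketConfig(n_persons=5_000, n_insurers=5, seed=42)
    panel_a, truth_a = simulate_market(cfg)
    panel_b, truth_b = simulate_market(cfg)
    pd.testing.assert_frame_equal(panel_a, panel_b)
    assert truth_a.inflow_mean_unpriced == truth_b.inflow_mean_unpriced


def test_switch_rate_near_default_three_percent():
    cfg = MarketConfig(n_persons=1_000_000, n_insurers=25, seed=8)
    pop = generate_population(cfg)
    assignments, _ = assign_and_switch(pop, cfg)
    lo, hi = _binomial_99_interval(0.031, len(pop))
    assert lo < assignments["switched"].mean() < hi


def test_no_selection_means_switching_independent_of_health():
    cfg = MarketConfig(n_persons=200_000, n_insurers=5, seed=9)
    pop = generate_population(cfg)
    assignments, truth = assign_and_switch(pop, cfg)
    u = pop["unpriced_effect"].to_numpy()
    s = assignments["switched"].to_numpy().astype(float)
    r = np.corrcoef(u, s)[0, 1]
    assert abs(r) < 3 / np.sqrt(len(pop))


def test_strong_selection_shifts_inflow_composition():
    """A large positive tilt for insurer 1 attracts the undercompensated:
    its inflow mean unpriced effect sits far above the population mean."""
    strengths = (0.01, 0.0, 0.0, 0.0, 0.0)
    cfg = MarketConfig(
        n_persons=100_000, n_insurers=5, seed=10, selection_strength=strengths
    )
    pop = generate_population(cfg)
    _, truth = assign_and_switch(pop, cfg)
    u = pop["unpriced_effect"].to_numpy()
    se = u.std() / np.sqrt(truth.inflow_n[1])
    assert truth.inflow_mean_unpriced[1] > truth.population_mean_unpriced + 6 * se


def test_zero_utilization_share_matches_default_calibration():
    cfg = MarketConfig(n_persons=100_000, n_insurers=5, seed=11)
    panel, _ = simulate_market(cfg)
    lo, hi = _binomial_99_interval(0.195, len(panel))
    assert lo < (panel["expenses"] == 0).mean() < hi


def test_mean_expenses_near_configured_scale():
    cfg = MarketConfig(n_persons=200_000, n_insurers=5, seed=12)
    panel, _ = simulate_market(cfg)
    assert abs(panel["expenses"].mean() - 1570.0) < 30.0


def test_degenerate_expense_distribution_hits_expectation():
    """With (near) zero dispersion, no zero mass and no unpriced effect,
    every expense equals the person's deterministic mean."""
    cfg = MarketConfig(
        n_persons=2_000,
        n_insurers=3,
        seed=13,
        zero_prob_base=0.0,
        zero_prob_morbidity=0.0,
        expense_gamma_shape=1e6,
        unpriced=UnpricedSpec(scale=0.0),
    )
    panel, _ = simulate_market(cfg)
    by_cell = panel.groupby(
        ["age_band", "sex", "region", "chronic"], observed=True
    )["expenses"]
    rel_spread = ((by_cell.max() - by_cell.min()) / by_cell.mean()).max()
    assert rel_spread < 0.02


def test_efficiency_scales_expenses_with_common_random_numbers():
    base = MarketConfig(n_persons=30_000, n_insurers=4, seed=14)
    perturbed = base.replace(efficiency_multipliers=(1.0, 0.9, 1.0, 1.0))
    p0, _ = simulate_market(base)
    p1, _ = simulate_market(perturbed)
    at_k = p0["insurer_id"].to_numpy() == 2
    e0, e1 = p0["expenses"].to_numpy(), p1["expenses"].to_numpy()
    # untouched insurers: draws bit-identical
    assert np.array_equal(e0[~at_k], e1[~at_k])
    # insurer 2: every positive expense scaled exactly by 0.9
    np.testing.assert_allclose(e1[at_k], 0.9 * e0[at_k], rtol=1e-12)


def test_rng_streams_are_independent():
    """Changing only efficiency leaves population and assignments
    bit-identical (separate child streams per stage)."""
    base = MarketConfig(n_persons=10_000, n_insurers=3, seed=15)
    other = base.replace(efficiency_multipliers=(0.8, 1.0, 1.2))
    pop_a, pop_b = generate_population(base), generate_population(other)
    pd.testing.assert_frame_equal(pop_a, pop_b)
    asg_a, _ = assign_and_switch(pop_a, base)
    asg_b, _ = assign_and_switch(pop_b, other)
    pd.testing.assert_frame_equal(asg_a, asg_b)


def test_ground_truth_matches_panel_recomputation():
    cfg = MarketConfig(
        n_persons=20_000,
        n_insurers=4,
        seed=16,
        selection_strength=(-0.002, 0.0, 0.001, 0.0),
    )
    panel, truth = simulate_market(cfg)
    redo = panel_ground_truth(panel, cfg)
    assert redo.inflow_n == truth.inflow_n
    assert redo.outflow_n == truth.outflow_n
    for j in range(1, 5):
        np.testing.assert_allclose(
            redo.inflow_mean_unpriced[j], truth.inflow_mean_unpriced[j], rtol=1e-12
        )
        np.testing.assert_allclose(
            redo.outflow_mean_unpriced[j], truth.outflow_mean_unpriced[j], rtol=1e-12
        )


def test_null_market_ground_truth_centered_at_zero():
    cfg = MarketConfig(n_persons=200_000, n_insurers=5, seed=17)
    pop = generate_population(cfg)
    _, truth = assign_and_switch(pop, cfg)
    sd_u = pop["unpriced_effect"].std()
    for j in range(1, 6):
        se = sd_u / np.sqrt(truth.inflow_n[j])
        assert abs(truth.inflow_overcompensation(j)) < 4 * se


def test_calibration_predicts_realized_inflow_mean():
    """The quadrature-based expected inflow composition matches a large
    simulation, and the solved tilt hits the +100 overcompensation target."""
    cfg = MarketConfig(n_persons=400_000, n_insurers=5, seed=18)
    s = calibrate_inflow_selection(cfg, insurer=1, target_overcompensation=100.0)
    assert s < 0  # courting the overcompensated means tilting to low u
    cfg2 = cfg.replace(selection_strength=(s, 0.0, 0.0, 0.0, 0.0))
    assert abs(expected_inflow_unpriced(cfg2, 1) + 100.0) < 1e-6
    pop = generate_population(cfg2)
    _, truth = assign_and_switch(pop, cfg2)
    sd_u = pop["unpriced_effect"].std()
    se = sd_u / np.sqrt(truth.inflow_n[1])
    assert abs(truth.inflow_overcompensation(1) - 100.0) < 4 * se
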