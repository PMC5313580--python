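"""Scenario presets and end-to-end pipeline orchestration.

Each preset exercises one named mechanism of the selection-measurement
problem:

* ``null-market`` — equal efficiency, no selection: every estimator
  should be centered at zero with nominal test size.
* ``efficiency-bias`` — efficiency multipliers spread over 0.9..1.1,
  no selection: the naive insurer means light up, the switcher
  estimates must not.
* ``recovery`` — selection tilted so that insurer 1's inflow has a
  known ground-truth overcompensation of +100: the switcher estimator
  must recover it.
* ``cancel-out`` — one insurer attracts both the over- and the
  undercompensated tail at once: its naive estimate stays near zero
  while the subgroup compensation rows are large and significant.
* ``unsuccessful-selection`` — every insurer courts the overcompensated
  equally hard: portfolios stay identical in composition, so all
  estimators read (near) zero although selection actions are everywhere.

Presets are sized at n = 200,000 persons so a full scenario runs in
seconds and replicate studies in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .config import MarketConfig
from .equalization import EqualizationModel, fit_equalization_model, predict_and_residualize
from .market import (
    GroundTruth,
    calibrate_inflow_selection,
    simulate_market,
)
from .metrics import (
    compensation_table,
    naive_insurer_estimate,
    overrepresentation_table,
    switcher_estimates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioPreset:
    """Named MarketConfig overrides plus the mechanism they demonstrate."""

    name: str
    overrides: dict[str, Any]
    narrative: str
    # overrides that need the base config (e.g. calibrated tilts)
    derive: Callable[[MarketConfig], dict[str, Any]] | None = None

    def build(self, n_persons: int | None = None, seed: int = 0) -> MarketConfig:
        cfg = MarketConfig(**self.overrides)
        if n_persons is not None:
            cfg = cfg.replace(n_persons=n_persons)
        cfg = cfg.replace(seed=seed)
        if self.derive is not None:
            cfg = cfg.replace(**self.derive(cfg))
        cfg.validate()
        return cfg


def _recovery_overrides(cfg: MarketConfig) -> dict[str, Any]:
    s = calibrate_inflow_selection(cfg, insurer=1, target_overcompensation=100.0)
    strengths = [0.0] * cfg.n_insurers
    strengths[0] = s
    return {"selection_strength": tuple(strengths)}


PRESETS: dict[str, ScenarioPreset] = {
    "null-market": ScenarioPreset(
        name="null-market",
        overrides=dict(n_persons=200_000, n_insurers=25),
        narrative="equal efficiency, no selection: all estimators null",
    ),
    "efficiency-bias": ScenarioPreset(
        name="efficiency-bias",
        overrides=dict(
            n_persons=200_000,
            n_insurers=5,
            efficiency_multipliers=(0.9, 0.95, 1.0, 1.05, 1.1),
        ),
        narrative="efficiency spread, no selection: naive estimates are "
        "biased, switcher estimates are not",
    ),
    "recovery": ScenarioPreset(
        name="recovery",
        overrides=dict(n_persons=200_000, n_insurers=5),
        narrative="insurer 1 courts the overcompensated so its inflow has "
        "ground-truth overcompensation +100; the switcher estimator must "
        "recover it",
        derive=_recovery_overrides,
    ),
    "cancel-out": ScenarioPreset(
        name="cancel-out",
        overrides=dict(
            n_persons=200_000,
            n_insurers=5,
            selection_abs_strength=(0.002, 0.0, 0.0, 0.0, 0.0),
        ),
        narrative="insurer 1 attracts both tails of the unpriced "
        "distribution: subgroup effects cancel in its portfolio mean",
    ),
    "unsuccessful-selection": ScenarioPreset(
        name="unsuccessful-selection",
        overrides=dict(
            n_persons=200_000,
            n_insurers=5,
            selection_strength=(-0.002, -0.002, -0.002, -0.002, -0.002),
        ),
        narrative="all insurers equally successful at courting the "
        "overcompensated: compositions stay equal, estimators read zero",
    ),
}


def preset_config(
    name: str, n_persons: int | None = None, seed: int = 0
) -> MarketConfig:
    if name not in PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name].build(n_persons=n_persons, seed=seed)


# --------------------------------------------------------------------- #
# pipeline


def default_groups(panel: pd.DataFrame, year: int) -> dict[str, pd.Series]:
    """Built-in selected groups, defined on year-(t-1) information the way
    published compensation tables define them: the morbidity flag, zero
    utilization in the prior year, and the sign of the unpriced effect
    (the latter available in synthetic panels only)."""
    rows = panel[panel["year"] == year].reset_index(drop=True)
    groups: dict[str, pd.Series] = {}
    if "chronic" in rows.columns:
        groups["chronic condition"] = rows["chronic"].astype(str) == "1"
        groups["no chronic condition"] = rows["chronic"].astype(str) == "0"
    groups["no utilization prior year"] = rows["expenses"] == 0.0
    if "unpriced_effect" in rows.columns:
        groups["unpriced effect > 0"] = rows["unpriced_effect"] > 0
        groups["unpriced effect <= 0"] = rows["unpriced_effect"] <= 0
    return groups


def run_pipeline(
    config: MarketConfig,
    model: EqualizationModel | None = None,
    p_share: float = 50.0,
    groups: Mapping[str, pd.Series] | None = None,
) -> dict[str, Any]:
    """simulate -> equalize (both years) -> all four estimators.

    With ``model`` supplied, the fixed coefficients are applied to both
    years without refitting; otherwise a model is fit per year.  Group
    membership is defined on year-(t-1) rows and evaluated on year-t
    residuals, so the groups line up row-by-row with the year-t records
    (the panel has the same persons in both years, ordered identically).

    Returns a bundle with the panel, ground truth, models, residuals per
    year, and the naive/switcher/group/overrepresentation tables.
    """
    y_prev, y_post = config.years
    panel, truth = simulate_market(config)
    adjusters = config.adjuster_names()
    if model is None:
        models = {
            y: fit_equalization_model(panel, adjusters, y, p_share)
            for y in config.years
        }
    else:
        models = {y: model for y in config.years}
    residuals = {
        y: predict_and_residualize(panel, models[y], y) for y in config.years
    }
    if groups is None:
        groups = default_groups(panel, y_prev)
    group_table = compensation_table(
        residuals[y_post],
        groups,
        overall_mean=models[y_post].overall_mean,
    )
    naive = naive_insurer_estimate(residuals[y_post])
    switcher = switcher_estimates(panel, residuals)
    panel_post = panel[panel["year"] == y_post].reset_index(drop=True)
    over_table = None
    if "unpriced_effect" in panel_post.columns:
        over_table = overrepresentation_table(
            panel_post, panel_post["unpriced_effect"] > 0
        )
    return {
        "config": config,
        "panel": panel,
        "ground_truth": truth,
        "models": models,
        "residuals": residuals,
        "group_table": group_table,
        "naive_table": naive,
        "switcher_table": switcher,
        "overrepresentation_table": over_table,
    }


# --------------------------------------------------------------------- #
# replicate studies


def replicate_switcher_study(
    config: MarketConfig,
    n_replicates: int,
    base_seed: int,
    model: EqualizationModel | None = None,
) -> pd.DataFrame:
    """Re-simulate ``config`` under seeds ``base_seed + r`` and collect the
    per-insurer switcher and naive estimates together with the realized
    ground truth, one row per (replicate, insurer)."""
    records = []
    for r in range(n_replicates):
        cfg = config.replace(seed=base_seed + r)
        panel, truth = simulate_market(cfg)
        adjusters = cfg.adjuster_names()
        if model is None:
            models = {
                y: fit_equalization_model(panel, adjusters, y) for y in cfg.years
            }
        else:
            models = {y: model for y in cfg.years}
        residuals = {
            y: predict_and_residualize(panel, models[y], y) for y in cfg.years
        }
        sw = switcher_estimates(panel, residuals, order="insurer_id")
        naive = naive_insurer_estimate(residuals[cfg.years[1]])
        for _, row in sw.iterrows():
            j = int(row["insurer_id"])
            records.append(
                {
                    "replicate": r,
                    "insurer_id": j,
                    "n_inflow": row["n_inflow"],
                    "inflow_overcompensation": row["inflow_overcompensation"],
                    "inflow_se": row["inflow_se"],
                    "inflow_p_value": row["inflow_p_value"],
                    "n_outflow": row["n_outflow"],
                    "outflow_overcompensation": row["outflow_overcompensation"],
                    "outflow_se": row["outflow_se"],
                    "outflow_p_value": row["outflow_p_value"],
                    "naive_overcompensation": naive.loc[
                        j, "mean_overcompensation"
                    ],
                    "naive_p_value": naive.loc[j, "p_value"],
                    "truth_inflow_overcompensation": truth.inflow_overcompensation(
                        j
                    ),
                    "truth_outflow_overcompensation": truth.outflow_overcompensation(
                        j
                    ),
                }
            )
    return pd.DataFrame(records)
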