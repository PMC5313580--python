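"""Synthetic two-year insurance-market panels with known ground truth.

The generator is deliberately modular: population characteristics, insurer
assignment/switching, and expense realization each consume an independent
RNG stream derived from the config seed, so that perturbing one block of
the configuration (say, one insurer's efficiency multiplier) leaves every
draw in the other blocks bit-identical.  That common-random-numbers
property is what makes counterfactual comparisons (an insurer at
efficiency 0.9 vs the same market at 1.0) exact rather than statistical.

Expenses follow a two-part model: a person-year is zero with a morbidity-
dependent probability, otherwise gamma-distributed with a log-linear mean
over the risk adjusters, shifted additively (in euros) by the person's
unpriced health component, and finally scaled by the enrolled insurer's
efficiency multiplier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ConfigError, MarketConfig

# child-stream keys; the literal values only need to be distinct
_STREAM_POPULATION = 11
_STREAM_SWITCHING = 23
_STREAM_EXPENSES = 37


def _rng(config: MarketConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# --------------------------------------------------------------------- #
# ground truth


@dataclass
class GroundTruth:
    """Realized selection and efficiency ground truth of one simulation.

    ``inflow_mean_unpriced[j]`` is the mean unpriced effect of persons who
    joined insurer j at the year boundary; ``outflow_mean_unpriced[j]`` of
    persons who left it.  The implied ground-truth *overcompensation* of a
    group is ``-(group mean unpriced - population mean unpriced)``: a
    perfectly fitted equalization model prices everything except u, so a
    group healthier than its risk profile (u below average) is
    overcompensated.
    """

    n_insurers: int
    efficiency_multipliers: tuple[float, ...]
    population_mean_unpriced: float
    inflow_n: dict[int, int] = field(default_factory=dict)
    inflow_mean_unpriced: dict[int, float] = field(default_factory=dict)
    outflow_n: dict[int, int] = field(default_factory=dict)
    outflow_mean_unpriced: dict[int, float] = field(default_factory=dict)

    def inflow_overcompensation(self, insurer: int) -> float:
        return -(self.inflow_mean_unpriced[insurer] - self.population_mean_unpriced)

    def outflow_overcompensation(self, insurer: int) -> float:
        return -(self.outflow_mean_unpriced[insurer] - self.population_mean_unpriced)

    def to_json(self, path: str) -> None:
        payload = {
            "n_insurers": self.n_insurers,
            "efficiency_multipliers": list(self.efficiency_multipliers),
            "population_mean_unpriced": self.population_mean_unpriced,
            "insurers": {
                str(j): {
                    "inflow_n": self.inflow_n.get(j, 0),
                    "inflow_mean_unpriced": self.inflow_mean_unpriced.get(
                        j, float("nan")
                    ),
                    "outflow_n": self.outflow_n.get(j, 0),
                    "outflow_mean_unpriced": self.outflow_mean_unpriced.get(
                        j, float("nan")
                    ),
                }
                for j in range(1, self.n_insurers + 1)
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        gt = cls(
            n_insurers=payload["n_insurers"],
            efficiency_multipliers=tuple(payload["efficiency_multipliers"]),
            population_mean_unpriced=payload["population_mean_unpriced"],
        )
        for key, rec in payload["insurers"].items():
            j = int(key)
            gt.inflow_n[j] = rec["inflow_n"]
            gt.inflow_mean_unpriced[j] = rec["inflow_mean_unpriced"]
            gt.outflow_n[j] = rec["outflow_n"]
            gt.outflow_mean_unpriced[j] = rec["outflow_mean_unpriced"]
        return gt


# --------------------------------------------------------------------- #
# population


def generate_population(config: MarketConfig) -> pd.DataFrame:
    """Draw person-level risk profiles.

    Returns a frame with ``person_id``, one categorical column per
    adjuster, and ``unpriced_effect`` (euro/year; ground truth, hidden
    from the estimators by default).  Deterministic given the config seed.
    """
    config.validate()
    rng = _rng(config, _STREAM_POPULATION)
    n = config.n_persons
    out = pd.DataFrame({"person_id": np.arange(n, dtype=np.int64)})
    for adj in config.adjusters:
        cum = np.cumsum(adj.probs)
        cum[-1] = 1.0
        codes = np.searchsorted(cum, rng.random(n), side="right")
        out[adj.name] = pd.Categorical.from_codes(
            codes.astype(np.int64), categories=list(adj.levels)
        )
    u = np.zeros(n)
    spec = config.unpriced
    if spec.scale > 0 and spec.prob_affected > 0:
        if spec.carrier_adjuster is not None:
            carrier = (
                out[spec.carrier_adjuster].to_numpy() == spec.carrier_level
            )
        else:
            carrier = np.ones(n, dtype=bool)
        affected = carrier & (rng.random(n) < spec.prob_affected)
        k = spec.gamma_shape
        u[affected] = spec.scale * (
            rng.standard_gamma(k, affected.sum()) - k
        )
    out["unpriced_effect"] = u
    return out


# --------------------------------------------------------------------- #
# assignment and switching


def assign_and_switch(
    population: pd.DataFrame, config: MarketConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Assign insurers in both years and realize switching.

    Year-(t-1) membership follows the configured market shares.  Each
    person switches with probability ``switch_rate``; with nonzero
    ``exit_strength`` the decision to leave insurer j is tilted on the
    person's unpriced effect through a logistic weight.  A switcher's
    destination among the other insurers has weight
    ``share_j * exp(s_j * u + a_j * |u|)``.  With all tilts zero,
    switching is independent of health by construction.

    Returns (assignments, ground truth); assignments has columns
    ``person_id``, ``insurer_y1``, ``insurer_y2``, ``switched``.
    """
    rng = _rng(config, _STREAM_SWITCHING)
    n = len(population)
    u = population["unpriced_effect"].to_numpy()
    K = config.n_insurers
    shares = np.asarray(config.shares)

    cum = np.cumsum(shares)
    cum[-1] = 1.0
    y1 = np.searchsorted(cum, rng.random(n), side="right").astype(np.int64) + 1

    exit_s = np.asarray(config.exit_strengths)
    if config.switch_rate in (0.0, 1.0) or not exit_s.any():
        p_switch = np.full(n, config.switch_rate)
    else:
        logit = np.log(config.switch_rate / (1.0 - config.switch_rate))
        z = np.clip(logit + exit_s[y1 - 1] * u, -30.0, 30.0)
        p_switch = 1.0 / (1.0 + np.exp(-z))
    switched = rng.random(n) < p_switch

    y2 = y1.copy()
    idx = np.flatnonzero(switched)
    if idx.size:
        s = np.asarray(config.strengths)
        a = np.asarray(config.abs_strengths)
        usw = u[idx]
        expo = np.clip(
            usw[:, None] * s[None, :] + np.abs(usw)[:, None] * a[None, :],
            -30.0,
            30.0,
        )
        w = shares[None, :] * np.exp(expo)
        w[np.arange(idx.size), y1[idx] - 1] = 0.0
        cw = np.cumsum(w, axis=1)
        r = rng.random(idx.size) * cw[:, -1]
        dest = (cw <= r[:, None]).sum(axis=1).astype(np.int64) + 1
        # guard against r landing exactly on the total weight
        np.clip(dest, 1, K, out=dest)
        y2[idx] = dest

    assignments = pd.DataFrame(
        {
            "person_id": population["person_id"].to_numpy(),
            "insurer_y1": y1,
            "insurer_y2": y2,
            "switched": switched,
        }
    )

    truth = GroundTruth(
        n_insurers=K,
        efficiency_multipliers=tuple(config.efficiency),
        population_mean_unpriced=float(u.mean()) if n else float("nan"),
    )
    for j in range(1, K + 1):
        m_in = switched & (y2 == j)
        m_out = switched & (y1 == j)
        truth.inflow_n[j] = int(m_in.sum())
        truth.outflow_n[j] = int(m_out.sum())
        truth.inflow_mean_unpriced[j] = (
            float(u[m_in].mean()) if truth.inflow_n[j] else float("nan")
        )
        truth.outflow_mean_unpriced[j] = (
            float(u[m_out].mean()) if truth.outflow_n[j] else float("nan")
        )
    return assignments, truth


# --------------------------------------------------------------------- #
# expenses


def _positive_mean(population: pd.DataFrame, config: MarketConfig) -> np.ndarray:
    """Per-person mean of the positive expense part at efficiency 1."""
    eta = np.full(len(population), config.intercept())
    for adj in config.adjusters:
        eff = np.asarray(adj.log_effects)
        codes = population[adj.name].cat.codes.to_numpy()
        eta += eff[codes]
    p0 = _zero_prob(population, config)
    mu = np.exp(eta) + population["unpriced_effect"].to_numpy() / (1.0 - p0)
    if np.any(mu <= 0):
        raise ConfigError(
            "configuration implies a nonpositive expense mean for "
            f"{int((mu <= 0).sum())} person(s)"
        )
    return mu


def _zero_prob(population: pd.DataFrame, config: MarketConfig) -> np.ndarray:
    p_flag, p_rest = config.zero_probs()
    if config.morbidity_adjuster is None:
        return np.full(len(population), config.zero_prob_base)
    flagged = (
        population[config.morbidity_adjuster].to_numpy() == config.morbidity_level
    )
    return np.where(flagged, p_flag, p_rest)


def realize_expenses(
    population: pd.DataFrame,
    assignments: pd.DataFrame,
    config: MarketConfig,
) -> pd.DataFrame:
    """Draw annual expenses for both years and emit the person-year panel.

    A person-year is zero with the morbidity-modulated zero probability,
    else ``efficiency[insurer] * Gamma(shape, mu/shape)`` where ``mu`` is
    the adjuster- and unpriced-shifted positive-part mean.  Efficiency
    multiplies the positive part only, so the zero mass stays
    interpretable as (lack of) utilization.
    """
    rng = _rng(config, _STREAM_EXPENSES)
    n = len(population)
    mu = _positive_mean(population, config)
    p0 = _zero_prob(population, config)
    eff = np.asarray(config.efficiency)
    k = config.expense_gamma_shape

    zero_u = rng.random((2, n))
    gamma_std = rng.standard_gamma(k, (2, n))

    frames = []
    for yi, (year, col) in enumerate(
        zip(config.years, ("insurer_y1", "insurer_y2"))
    ):
        insurer = assignments[col].to_numpy()
        expenses = np.where(
            zero_u[yi] < p0,
            0.0,
            eff[insurer - 1] * mu / k * gamma_std[yi],
        )
        frame = pd.DataFrame(
            {
                "person_id": population["person_id"].to_numpy(),
                "year": np.full(n, year, dtype=np.int64),
                "insurer_id": insurer,
            }
        )
        for adj in config.adjusters:
            frame[adj.name] = population[adj.name].array
        frame["unpriced_effect"] = population["unpriced_effect"].to_numpy()
        frame["expenses"] = expenses
        frames.append(frame)
    panel = pd.concat(frames, ignore_index=True)
    return panel


def simulate_market(config: MarketConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a complete two-year panel plus ground truth."""
    population = generate_population(config)
    assignments, truth = assign_and_switch(population, config)
    panel = realize_expenses(population, assignments, config)
    return panel, truth


# --------------------------------------------------------------------- #
# selection calibration


def expected_inflow_unpriced(config: MarketConfig, insurer: int) -> float:
    """Expected mean unpriced effect among switchers joining ``insurer``.

    Computed by numerical integration over the unpriced mixture, assuming
    exit tilts are zero (the switch decision is health-independent), which
    holds for the shipped scenario presets.
    """
    u_grid, dens, mass0 = _unpriced_grid(config)
    w_grid = _inflow_weight(config, insurer, u_grid)
    w_zero = _inflow_weight(config, insurer, np.array([0.0]))[0]
    num = np.trapezoid(u_grid * w_grid * dens, u_grid)
    den = mass0 * w_zero + np.trapezoid(w_grid * dens, u_grid)
    return float(num / den)


def _unpriced_grid(
    config: MarketConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    spec = config.unpriced
    if spec.carrier_adjuster is not None:
        adj = config.adjuster_by_name(spec.carrier_adjuster)
        p_carrier = adj.probs[adj.levels.index(spec.carrier_level)]
    else:
        p_carrier = 1.0
    p_nonzero = p_carrier * spec.prob_affected
    k = spec.gamma_shape
    x = np.linspace(1e-9, k + 40.0 * max(1.0, np.sqrt(k)), 4001)
    u = spec.scale * (x - k)
    # density in u-units: pdf_x / |du/dx|, du/dx = scale
    dens = p_nonzero * stats.gamma.pdf(x, k) / spec.scale
    return u, dens, 1.0 - p_nonzero


def _inflow_weight(
    config: MarketConfig, insurer: int, u: np.ndarray
) -> np.ndarray:
    shares = np.asarray(config.shares)
    s = np.asarray(config.strengths)
    a = np.asarray(config.abs_strengths)
    j = insurer - 1
    w_j = shares[j] * np.exp(
        np.clip(s[j] * u + a[j] * np.abs(u), -30.0, 30.0)
    )
    total = np.zeros_like(u)
    w_all = shares[None, :] * np.exp(
        np.clip(
            u[:, None] * s[None, :] + np.abs(u)[:, None] * a[None, :],
            -30.0,
            30.0,
        )
    )
    sum_all = w_all.sum(axis=1)
    for o in range(len(shares)):
        if o == j:
            continue
        total += shares[o] * w_j / (sum_all - w_all[:, o])
    return total


def calibrate_inflow_selection(
    config: MarketConfig,
    insurer: int = 1,
    target_overcompensation: float = 100.0,
) -> float:
    """Solve for the linear selection strength of ``insurer`` that makes
    the *expected* ground-truth inflow overcompensation equal the target.

    A positive target (the inflow is overcompensated, i.e. healthier than
    priced) corresponds to a negative tilt that courts low-u persons.
    Other insurers' strengths are taken from the config.
    """
    target_u = -float(target_overcompensation)

    def f(s: float) -> float:
        strengths = list(config.strengths)
        strengths[insurer - 1] = s
        cfg = config.replace(selection_strength=tuple(strengths))
        return expected_inflow_unpriced(cfg, insurer) - target_u

    lo, hi = -1e-3, 1e-3
    for _ in range(40):
        if f(lo) * f(hi) < 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise ValueError("could not bracket the selection strength")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def panel_ground_truth(panel: pd.DataFrame, config: MarketConfig) -> GroundTruth:
    """Recompute ground truth directly from an emitted panel (consistency
    oracle for :func:`assign_and_switch`); requires the truth column."""
    y1, y2 = config.years
    wide = panel.pivot(index="person_id", columns="year", values="insurer_id")
    u = (
        panel[panel["year"] == y1]
        .set_index("person_id")["unpriced_effect"]
        .reindex(wide.index)
        .to_numpy()
    )
    a = wide[y1].to_numpy()
    b = wide[y2].to_numpy()
    switched = a != b
    truth = GroundTruth(
        n_insurers=config.n_insurers,
        efficiency_multipliers=tuple(config.efficiency),
        population_mean_unpriced=float(u.mean()),
    )
    for j in range(1, config.n_insurers + 1):
        m_in = switched & (b == j)
        m_out = switched & (a == j)
        truth.inflow_n[j] = int(m_in.sum())
        truth.outflow_n[j] = int(m_out.sum())
        truth.inflow_mean_unpriced[j] = (
            float(u[m_in].mean()) if truth.inflow_n[j] else float("nan")
        )
        truth.outflow_mean_unpriced[j] = (
            float(u[m_out].mean()) if truth.outflow_n[j] else float("nan")
        )
    return truth
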