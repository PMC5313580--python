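"""Market configuration for the synthetic two-year insurance panel.

The simulator emulates a regulated health-insurance market of the Dutch
type: a large insured population, ~25 risk-bearing insurers, annual open
enrollment with a few percent of the population switching insurer, and a
regulator-run risk-equalization scheme whose risk adjusters capture most
but not all predictable expense variation.  The part they miss — the
*unpriced* health component — is the ground-truth quantity every selection
estimator in this package tries to recover.

Monetary quantities are in abstract euro-like units per person-year; the
default calibration puts mean annual expenses at 1570.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a market configuration is internally inconsistent."""


@dataclass(frozen=True)
class AdjusterSpec:
    """One categorical risk adjuster.

    ``log_effects`` are multiplicative effects of each level on the mean of
    the positive expense part, on the log scale; the first level is the
    reference.  Probabilities are the population shares of the levels.
    """

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    log_effects: tuple[float, ...]

    def validate(self) -> None:
        k = len(self.levels)
        if k < 2:
            raise ConfigError(f"adjuster {self.name!r}: needs at least 2 levels")
        if len(self.probs) != k or len(self.log_effects) != k:
            raise ConfigError(
                f"adjuster {self.name!r}: levels, probs and log_effects must "
                f"have equal length"
            )
        if any(p < 0 for p in self.probs) or not math.isclose(
            sum(self.probs), 1.0, abs_tol=1e-9
        ):
            raise ConfigError(
                f"adjuster {self.name!r}: category probabilities must be "
                f"nonnegative and sum to 1 (got {sum(self.probs)!r})"
            )


@dataclass(frozen=True)
class UnpricedSpec:
    """Distribution of the unpriced health component u (euro/year).

    A mixture: a point mass at zero ("fully priced" persons) plus, for a
    fraction ``prob_affected`` of the carrier group, a centered-gamma draw
    ``scale * (Gamma(gamma_shape) - gamma_shape)``.  The draw has mean 0,
    standard deviation ``scale * sqrt(gamma_shape)``, is right-skewed (a
    minority of carriers is far more expensive than their risk group
    suggests) and is bounded below at ``-gamma_shape * scale``, which keeps
    implied expense means positive by construction.

    ``carrier_adjuster``/``carrier_level`` restrict the nonzero component to
    one adjuster cell (default: the morbidity flag), emulating unpriced
    severity variation *within* the chronically ill.  Set
    ``carrier_adjuster=None`` to let the whole population carry it.
    """

    prob_affected: float = 0.8
    gamma_shape: float = 2.0
    scale: float = 500.0
    carrier_adjuster: str | None = "chronic"
    carrier_level: str = "1"

    @property
    def min_value(self) -> float:
        return -self.gamma_shape * self.scale

    @property
    def sd(self) -> float:
        return self.scale * math.sqrt(self.gamma_shape)

    def validate(self) -> None:
        if not 0.0 <= self.prob_affected <= 1.0:
            raise ConfigError("unpriced.prob_affected must be in [0, 1]")
        if self.gamma_shape <= 0 or self.scale < 0:
            raise ConfigError("unpriced gamma_shape must be > 0 and scale >= 0")


def default_adjusters() -> tuple[AdjusterSpec, ...]:
    """Adjusters resembling the Dutch equalization model's demographic and
    morbidity blocks: age bands, sex, region, and a chronic-condition flag
    (population prevalence 31.5%)."""
    return (
        AdjusterSpec(
            name="age_band",
            levels=("0-17", "18-34", "35-49", "50-64", "65-74", "75+"),
            probs=(0.20, 0.22, 0.21, 0.19, 0.10, 0.08),
            log_effects=(-0.45, -0.35, -0.10, 0.0, 0.45, 0.75),
        ),
        AdjusterSpec(
            name="sex",
            levels=("F", "M"),
            probs=(0.505, 0.495),
            log_effects=(0.0, -0.08),
        ),
        AdjusterSpec(
            name="region",
            levels=("north", "east", "south", "west"),
            probs=(0.20, 0.30, 0.25, 0.25),
            log_effects=(0.0, 0.03, -0.02, 0.05),
        ),
        AdjusterSpec(
            name="chronic",
            levels=("0", "1"),
            probs=(0.685, 0.315),
            log_effects=(0.0, 1.10),
        ),
    )


@dataclass(frozen=True)
class MarketConfig:
    """Full specification of a simulated two-year market; the simulator's
    ground truth.

    Attributes
    ----------
    n_persons, n_insurers:
        Population and market size.  Insurer ids run 1..n_insurers.
    years:
        The two panel years (t-1, t); switching happens at one instant
        between them.
    adjusters:
        Risk-adjuster definitions (see :class:`AdjusterSpec`).
    unpriced:
        Distribution of the unpriced health component.
    zero_prob_base:
        Marginal probability of zero annual expenses (no utilization).
    zero_prob_morbidity:
        Zero-expense probability for persons with the morbidity flag; the
        probability for the rest is solved so the marginal equals
        ``zero_prob_base``.
    expense_gamma_shape:
        Shape of the gamma positive-expense part (cv = shape**-0.5).
    mean_expenses:
        Target marginal mean of annual expenses at efficiency 1.
    market_shares:
        Year-(t-1) market shares; ``None`` = equal shares.
    efficiency_multipliers:
        Per-insurer positive factors scaling the positive expense part of
        enrollees; ``None`` = all 1.
    switch_rate:
        Annual switching probability (default 0.031 ~ 500k switchers on a
        16M market).
    selection_strength, selection_abs_strength:
        Per-insurer destination-choice tilts: a switcher's destination
        weight for insurer j is proportional to
        ``share_j * exp(s_j * u + a_j * |u|)``.  ``s_j < 0`` courts the
        overcompensated (healthy); ``a_j > 0`` attracts both tails at once
        (the cancel-out mechanism).
    exit_strength:
        Per-insurer logit tilt of the *decision to leave* on u; all-zero
        means switching is independent of health.
    seed:
        Base RNG seed; population, switching and expense draws use
        independent child streams.
    """

    n_persons: int = 200_000
    n_insurers: int = 25
    years: tuple[int, int] = (2008, 2009)
    adjusters: tuple[AdjusterSpec, ...] = field(default_factory=default_adjusters)
    unpriced: UnpricedSpec = field(default_factory=UnpricedSpec)
    zero_prob_base: float = 0.195
    zero_prob_morbidity: float = 0.02
    morbidity_adjuster: str | None = "chronic"
    morbidity_level: str = "1"
    expense_gamma_shape: float = 0.5
    mean_expenses: float = 1570.0
    market_shares: tuple[float, ...] | None = None
    efficiency_multipliers: tuple[float, ...] | None = None
    switch_rate: float = 0.031
    selection_strength: tuple[float, ...] | None = None
    selection_abs_strength: tuple[float, ...] | None = None
    exit_strength: tuple[float, ...] | None = None
    seed: int = 0

    # ------------------------------------------------------------------ #
    # derived quantities

    def adjuster_by_name(self, name: str) -> AdjusterSpec:
        for a in self.adjusters:
            if a.name == name:
                return a
        raise ConfigError(f"no adjuster named {name!r}")

    @property
    def shares(self) -> tuple[float, ...]:
        if self.market_shares is None:
            return tuple([1.0 / self.n_insurers] * self.n_insurers)
        return self.market_shares

    @property
    def efficiency(self) -> tuple[float, ...]:
        if self.efficiency_multipliers is None:
            return tuple([1.0] * self.n_insurers)
        return self.efficiency_multipliers

    @property
    def strengths(self) -> tuple[float, ...]:
        if self.selection_strength is None:
            return tuple([0.0] * self.n_insurers)
        return self.selection_strength

    @property
    def abs_strengths(self) -> tuple[float, ...]:
        if self.selection_abs_strength is None:
            return tuple([0.0] * self.n_insurers)
        return self.selection_abs_strength

    @property
    def exit_strengths(self) -> tuple[float, ...]:
        if self.exit_strength is None:
            return tuple([0.0] * self.n_insurers)
        return self.exit_strength

    def zero_probs(self) -> tuple[float, float]:
        """(p0 for morbidity-flagged persons, p0 for the rest).

        Solved so the population marginal equals ``zero_prob_base``.  When
        no morbidity adjuster is configured both equal the base.
        """
        if self.morbidity_adjuster is None:
            return (self.zero_prob_base, self.zero_prob_base)
        adj = self.adjuster_by_name(self.morbidity_adjuster)
        idx = adj.levels.index(self.morbidity_level)
        prev = adj.probs[idx]
        p_flag = self.zero_prob_morbidity
        if prev >= 1.0:
            return (p_flag, p_flag)
        p_rest = (self.zero_prob_base - prev * p_flag) / (1.0 - prev)
        if not 0.0 <= p_rest < 1.0:
            raise ConfigError(
                "zero_prob_base / zero_prob_morbidity imply an out-of-range "
                f"zero probability {p_rest:.4f} for unflagged persons"
            )
        return (p_flag, p_rest)

    def intercept(self) -> float:
        """Log-scale intercept of the positive-expense mean, calibrated so
        the marginal mean of annual expenses equals ``mean_expenses`` at
        efficiency 1 (the unpriced component has mean zero)."""
        p_flag, p_rest = self.zero_probs()
        factor = 1.0
        for adj in self.adjusters:
            if adj.name == self.morbidity_adjuster:
                # zero probability depends on this adjuster: fold it in
                s = 0.0
                for lev, p, b in zip(adj.levels, adj.probs, adj.log_effects):
                    p0 = p_flag if lev == self.morbidity_level else p_rest
                    s += p * (1.0 - p0) * math.exp(b)
                factor *= s
            else:
                factor *= sum(
                    p * math.exp(b) for p, b in zip(adj.probs, adj.log_effects)
                )
        if self.morbidity_adjuster is None:
            factor *= 1.0 - self.zero_prob_base
        if factor <= 0:
            raise ConfigError("adjuster specification implies nonpositive mean")
        return math.log(self.mean_expenses / factor)

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be >= 0")
        if self.n_insurers < 1:
            raise ConfigError("n_insurers must be >= 1")
        if len(self.years) != 2 or self.years[0] >= self.years[1]:
            raise ConfigError("years must be an increasing pair (t-1, t)")
        names = [a.name for a in self.adjusters]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate adjuster names")
        for adj in self.adjusters:
            adj.validate()
        self.unpriced.validate()
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ConfigError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.zero_prob_base < 1.0:
            raise ConfigError("zero_prob_base must be in [0, 1)")
        if not 0.0 <= self.zero_prob_morbidity < 1.0:
            raise ConfigError("zero_prob_morbidity must be in [0, 1)")
        if self.expense_gamma_shape <= 0:
            raise ConfigError("expense_gamma_shape must be > 0")
        if self.mean_expenses <= 0:
            raise ConfigError("mean_expenses must be > 0")
        for name, vec in (
            ("market_shares", self.market_shares),
            ("efficiency_multipliers", self.efficiency_multipliers),
            ("selection_strength", self.selection_strength),
            ("selection_abs_strength", self.selection_abs_strength),
            ("exit_strength", self.exit_strength),
        ):
            if vec is not None and len(vec) != self.n_insurers:
                raise ConfigError(f"{name} must have length n_insurers")
        if any(e <= 0 for e in self.efficiency):
            raise ConfigError("efficiency_multipliers must be > 0")
        if self.market_shares is not None:
            if any(s < 0 for s in self.market_shares) or not math.isclose(
                sum(self.market_shares), 1.0, abs_tol=1e-9
            ):
                raise ConfigError("market_shares must be nonnegative and sum to 1")
        self.zero_probs()
        self._check_positive_mean()

    def _check_positive_mean(self) -> None:
        """The most negative possible unpriced draw must not push any
        person's implied positive-part mean below zero."""
        if self.unpriced.scale == 0 or self.unpriced.prob_affected == 0:
            return
        b0 = self.intercept()
        p_flag, p_rest = self.zero_probs()
        # minimum log-linear predictor over carrier cells
        eta_min = b0
        for adj in self.adjusters:
            if (
                self.unpriced.carrier_adjuster is not None
                and adj.name == self.unpriced.carrier_adjuster
            ):
                idx = adj.levels.index(self.unpriced.carrier_level)
                eta_min += adj.log_effects[idx]
            else:
                eta_min += min(adj.log_effects)
        if self.unpriced.carrier_adjuster == self.morbidity_adjuster and (
            self.unpriced.carrier_level == self.morbidity_level
        ):
            p0 = p_flag
        else:
            p0 = max(p_flag, p_rest)
        worst = math.exp(eta_min) + self.unpriced.min_value / (1.0 - p0)
        if worst <= 0:
            raise ConfigError(
                "unpriced-effect distribution implies a negative expense mean "
                f"for the cheapest carrier cell (min mean {worst:.1f}); reduce "
                "unpriced.scale or gamma_shape"
            )

    # ------------------------------------------------------------------ #
    # (de)serialization

    def replace(self, **kwargs: Any) -> "MarketConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["adjusters"] = [dataclasses.asdict(a) for a in self.adjusters]
        d["unpriced"] = dataclasses.asdict(self.unpriced)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MarketConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "adjusters" in d:
            d["adjusters"] = tuple(
                AdjusterSpec(
                    name=a["name"],
                    levels=tuple(str(x) for x in a["levels"]),
                    probs=tuple(float(x) for x in a["probs"]),
                    log_effects=tuple(float(x) for x in a["log_effects"]),
                )
                for a in d["adjusters"]
            )
        if "unpriced" in d and not isinstance(d["unpriced"], UnpricedSpec):
            d["unpriced"] = UnpricedSpec(**d["unpriced"])
        for key in (
            "years",
            "market_shares",
            "efficiency_multipliers",
            "selection_strength",
            "selection_abs_strength",
            "exit_strength",
        ):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "MarketConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a YAML mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]

    def adjuster_names(self) -> list[str]:
        return [a.name for a in self.adjusters]
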