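"""Risk-equalization model: fit, prediction, residuals and payments.

The equalization formula is a linear model of annual expenses on
dummy-encoded risk adjusters, fit by unweighted OLS on the individual
level for one year.  Core identities used throughout the package:

* ``residual      = actual - predicted``
* ``overcompensation = predicted - actual = -residual``
  (negative overcompensation is undercompensation)
* ``payment       = predicted - (p/100) * m``

where ``p`` is the payment share (0 in Israel, 50 in the Netherlands,
100 in Switzerland) and ``m`` the overall mean of actual expenses in the
fit year.  Predicted values (and hence payments) may be negative: an
insurer then pays into the equalization fund for that person.

A model may also be supplied as fixed coefficients (JSON) and applied
without refitting, the way a regulator applies an equalization model that
was estimated elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required panel column is missing or malformed."""


class CollinearityError(ValueError):
    """The dummy design is rank deficient after level dropping."""


@dataclass
class EqualizationModel:
    """Dummy-encoded linear equalization formula.

    ``coefficients[adjuster][level]`` holds one euro-scale coefficient per
    level; the reference level (first seen at fit) is stored explicitly
    with coefficient 0.  ``overall_mean`` is m, the fit-year mean of
    actual expenses; ``p_share`` is the payment parameter p in percent.
    """

    adjusters: tuple[str, ...]
    intercept: float
    coefficients: dict[str, dict[str, float]]
    p_share: float
    overall_mean: float
    fit_year: int
    dropped_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_share <= 100.0:
            raise ValueError("p_share must be in [0, 100]")
        if self.overall_mean < 0:
            raise ValueError("overall_mean must be >= 0")

    # ------------------------------------------------------------------ #

    def predict(self, panel: pd.DataFrame) -> np.ndarray:
        """Predicted expenses per row.

        Levels unseen at fit time map to the reference level (coefficient
        0); the occurrences are counted and logged so prediction is total.
        """
        pred = np.full(len(panel), self.intercept)
        unseen_total = 0
        for name in self.adjusters:
            if name not in panel.columns:
                raise SchemaError(f"panel is missing adjuster column {name!r}")
            coeffs = self.coefficients[name]
            col = panel[name]
            if isinstance(col.dtype, pd.CategoricalDtype):
                cats = col.cat.categories.astype(str)
                lut = np.array(
                    [coeffs.get(c, np.nan) for c in cats], dtype=float
                )
                mapped = lut[col.cat.codes.to_numpy()]
            else:
                mapped = (
                    col.astype(str).map(coeffs).to_numpy(dtype=float)
                )
            unseen = np.isnan(mapped)
            if unseen.any():
                unseen_total += int(unseen.sum())
                logger.warning(
                    "adjuster %r: %d rows with levels unseen at fit mapped "
                    "to the reference level",
                    name,
                    int(unseen.sum()),
                )
                mapped = np.nan_to_num(mapped)
            pred += mapped
        self._last_unseen_count = unseen_total
        return pred

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "adjusters": list(self.adjusters),
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "p_share": self.p_share,
                    "overall_mean": self.overall_mean,
                    "fit_year": self.fit_year,
                    "dropped_levels": self.dropped_levels,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "EqualizationModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            adjusters=tuple(d["adjusters"]),
            intercept=float(d["intercept"]),
            coefficients={
                a: {str(k): float(v) for k, v in levels.items()}
                for a, levels in d["coefficients"].items()
            },
            p_share=float(d["p_share"]),
            overall_mean=float(d["overall_mean"]),
            fit_year=int(d["fit_year"]),
            dropped_levels={
                a: list(v) for a, v in d.get("dropped_levels", {}).items()
            },
        )


# --------------------------------------------------------------------- #


def _design(
    panel: pd.DataFrame, adjusters: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, str]], dict[str, list[str]], dict[str, list[str]]]:
    """Intercept + dummy design for the non-reference levels.

    Returns (X, column labels, kept levels per adjuster with the reference
    first, dropped levels per adjuster).  Declared levels with zero
    observations are dropped with a warning.
    """
    n = len(panel)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[tuple[str, str]] = [("_intercept", "")]
    kept: dict[str, list[str]] = {}
    dropped: dict[str, list[str]] = {}
    for name in adjusters:
        if name not in panel.columns:
            raise SchemaError(f"panel is missing adjuster column {name!r}")
        col = panel[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            declared = list(col.cat.categories.astype(str))
            codes = col.cat.codes.to_numpy()
            counts = np.bincount(codes[codes >= 0], minlength=len(declared))
            observed = {declared[i] for i in range(len(declared)) if counts[i]}
            vals = None
        else:
            vals = col.astype(str).to_numpy()
            declared = sorted(pd.unique(vals))
            observed = set(declared)
            codes = None
        levels = [lev for lev in declared if lev in observed]
        gone = [lev for lev in declared if lev not in observed]
        if gone:
            dropped[name] = gone
            logger.warning(
                "adjuster %r: dropping unobserved level(s) %s", name, gone
            )
        if len(levels) < 1:
            raise SchemaError(f"adjuster {name!r} has no observed levels")
        kept[name] = levels
        for lev in levels[1:]:
            if codes is not None:
                cols.append((codes == declared.index(lev)).astype(float))
            else:
                cols.append((vals == lev).astype(float))
            labels.append((name, lev))
    return np.column_stack(cols), labels, kept, dropped


def fit_equalization_model(
    panel: pd.DataFrame,
    adjusters: Sequence[str],
    fit_year: int,
    p_share: float = 50.0,
) -> EqualizationModel:
    """Fit the equalization formula by OLS on one year of the panel.

    ``overall_mean`` is set to the fit-year mean of *actual* expenses
    (which equals mean predicted in-sample under OLS with an intercept).
    """
    for req in ("year", "expenses"):
        if req not in panel.columns:
            raise SchemaError(f"panel is missing column {req!r}")
    rows = panel[panel["year"] == fit_year]
    if rows.empty:
        raise SchemaError(f"panel has no rows for fit year {fit_year}")
    X, labels, kept, dropped = _design(rows, adjusters)
    y = rows["expenses"].to_numpy(dtype=float)
    # normal equations: the 0/1 dummy design is well conditioned and the
    # Gram matrix is tiny, which keeps repeated refits cheap
    xtx = X.T @ X
    xty = X.T @ y
    rank = np.linalg.matrix_rank(xtx, hermitian=True)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, labels)
        raise CollinearityError(
            "dummy design is rank deficient; collinear columns: "
            + ", ".join(f"{a}={lev}" for a, lev in bad)
        )
    beta = np.linalg.solve(xtx, xty)
    coefficients: dict[str, dict[str, float]] = {}
    beta_by_label = dict(zip(labels, beta))
    for name in adjusters:
        coefficients[name] = {kept[name][0]: 0.0}
        for lev in kept[name][1:]:
            coefficients[name][lev] = float(beta_by_label[(name, lev)])
    return EqualizationModel(
        adjusters=tuple(adjusters),
        intercept=float(beta[0]),
        coefficients=coefficients,
        p_share=float(p_share),
        overall_mean=float(y.mean()),
        fit_year=int(fit_year),
        dropped_levels=dropped,
    )


def _collinear_columns(
    X: np.ndarray, labels: list[tuple[str, str]]
) -> list[tuple[str, str]]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [labels[piv[i]] for i in range(len(diag)) if diag[i] < tol]


def equalization_payment(
    predicted: float | np.ndarray, model: EqualizationModel
) -> float | np.ndarray:
    """Equalization payment: predicted expenses minus p% of the overall
    mean.  Negative values are paid *to* the fund."""
    return predicted - (model.p_share / 100.0) * model.overall_mean


def predict_and_residualize(
    panel: pd.DataFrame,
    model: EqualizationModel,
    target_year: int,
) -> pd.DataFrame:
    """Apply a (fitted or supplied) model to one panel year.

    Returns one row per person-year with ``actual``, ``predicted``,
    ``residual`` (= actual - predicted), ``overcompensation`` (= -residual)
    and ``payment``.
    """
    rows = panel[panel["year"] == target_year]
    if rows.empty:
        raise SchemaError(f"panel has no rows for year {target_year}")
    predicted = model.predict(rows)
    actual = rows["expenses"].to_numpy(dtype=float)
    residual = actual - predicted
    out = pd.DataFrame(
        {
            "person_id": rows["person_id"].to_numpy(),
            "year": rows["year"].to_numpy(),
            "insurer_id": rows["insurer_id"].to_numpy(),
            "actual": actual,
            "predicted": predicted,
            "residual": residual,
            "overcompensation": -residual,
            "payment": equalization_payment(predicted, model),
        }
    )
    out.attrs["n_unseen_levels"] = getattr(model, "_last_unseen_count", 0)
    return out
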