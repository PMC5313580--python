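"""Measures of risk selection and their significance tests.

Four estimators, all reported on the *overcompensation* scale
(predicted minus actual expenses; negative = undercompensation):

* group compensation statistics — mean overcompensation, predictive
  ratio (mean predicted / mean actual) and reduction versus the
  no-equalization benchmark for a selected group of insured;
* overrepresentation index — a group's share inside one insurer divided
  by its population share, with an exact binomial test;
* naive insurer estimate — mean overcompensation over all of an
  insurer's enrollees.  Documented as *efficiency-confounded*: an
  efficient insurer shows positive overcompensation without any
  selection;
* switcher estimates — for insurer X, the mean overcompensation of its
  new enrollees in the year *before* the switch and of its disenrollees
  in the year *after* the switch.  Those expenses were incurred at other
  insurers, so X's own efficiency cannot contaminate the estimate.

Tests are one-sample two-sided tests of mean residual zero, applied per
group/insurer without multiple-testing correction (a Bonferroni toggle
exists but defaults off, matching how per-insurer stars are usually
reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

_NORMAL_APPROX_N = 10_000


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    n: int
    degenerate: bool


def significance_test(values: np.ndarray, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of mean == ``popmean``.

    For very large samples (n > 10^4) the normal approximation is used.
    Zero-variance samples return p = 1 with the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("significance_test requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return TestResult(float("nan"), 1.0, n, True)
    if n > _NORMAL_APPROX_N:
        t = (x.mean() - popmean) / (sd / np.sqrt(n))
        p = 2.0 * special.ndtr(-abs(t))
        return TestResult(float(t), float(p), n, False)
    t, p = stats.ttest_1samp(x, popmean)
    return TestResult(float(t), float(p), n, False)


# --------------------------------------------------------------------- #
# group compensation (Table-2-style rows)


@dataclass
class CompensationRow:
    """Compensation statistics for one selected group of insured."""

    group_label: str
    n_members: int
    population_share: float
    mean_actual: float
    mean_predicted: float
    mean_overcompensation: float
    predictive_ratio: float  # NaN when mean actual is 0
    reduction_vs_no_equalization: float
    p_value: float
    significant_05: bool
    significant_01: bool
    degenerate: bool = False


def group_compensation(
    residuals: pd.DataFrame,
    member: np.ndarray | pd.Series,
    overall_mean: float,
    group_label: str = "group",
) -> CompensationRow:
    """Compensation statistics for the group selected by boolean ``member``
    (aligned with ``residuals``, one year of residual records).

    ``overall_mean`` is m, the no-equalization benchmark prediction: the
    reduction column compares the group's overcompensation against
    ``m - mean actual``, the overcompensation it would have if every
    person were predicted at the overall mean.
    """
    mask = np.asarray(member, dtype=bool)
    if mask.shape[0] != len(residuals):
        raise ValueError("membership mask must align with the residual frame")
    sub = residuals.loc[mask]
    if sub.empty:
        raise ValueError(f"group {group_label!r} is empty")
    mean_actual = float(sub["actual"].to_numpy().mean())
    mean_predicted = float(sub["predicted"].to_numpy().mean())
    over = mean_predicted - mean_actual
    if mean_actual > 0:
        pr = mean_predicted / mean_actual
    else:
        pr = float("nan")
        logger.warning(
            "group %r: mean actual expenses are 0; predictive ratio "
            "unavailable",
            group_label,
        )
    u_none = overall_mean - mean_actual
    if u_none != 0.0:
        reduction = 1.0 - abs(over) / abs(u_none)
    else:
        reduction = float("nan")
    res = sub["residual"].to_numpy()
    if res.size >= 2:
        test = significance_test(res)
    else:
        test = TestResult(float("nan"), float("nan"), res.size, True)
    return CompensationRow(
        group_label=group_label,
        n_members=len(sub),
        population_share=len(sub) / len(residuals),
        mean_actual=mean_actual,
        mean_predicted=mean_predicted,
        mean_overcompensation=over,
        predictive_ratio=pr,
        reduction_vs_no_equalization=reduction,
        p_value=test.p_value,
        significant_05=bool(test.p_value < 0.05),
        significant_01=bool(test.p_value < 0.01),
        degenerate=test.degenerate,
    )


def compensation_table(
    residuals: pd.DataFrame,
    groups: Mapping[str, np.ndarray | pd.Series],
    overall_mean: float,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Stack :func:`group_compensation` rows into a table (one row per
    group).  With ``bonferroni=True`` the star thresholds are divided by
    the number of groups."""
    rows = [
        group_compensation(residuals, m, overall_mean, label)
        for label, m in groups.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if bonferroni and len(rows):
        k = len(rows)
        df["significant_05"] = df["p_value"] < 0.05 / k
        df["significant_01"] = df["p_value"] < 0.01 / k
    return df


# --------------------------------------------------------------------- #
# overrepresentation


@dataclass
class OverrepresentationResult:
    insurer_id: int
    n_insurer: int
    n_members_in_insurer: int
    insurer_share: float
    population_share: float
    index: float  # NaN when the population share is 0
    p_value: float
    significant_05: bool


def overrepresentation_index(
    panel_year: pd.DataFrame,
    insurer_id: int,
    member: np.ndarray | pd.Series,
) -> OverrepresentationResult:
    """Ratio of a group's share within one insurer to its population
    share, with an exact binomial test against the population share."""
    mask = np.asarray(member, dtype=bool)
    if mask.shape[0] != len(panel_year):
        raise ValueError("membership mask must align with the panel year")
    ins = panel_year["insurer_id"].to_numpy() == insurer_id
    n_ins = int(ins.sum())
    if n_ins == 0:
        raise ValueError(f"insurer {insurer_id} has no enrollees in this year")
    pop_share = float(mask.mean())
    k = int((mask & ins).sum())
    ins_share = k / n_ins
    if pop_share == 0.0:
        logger.warning(
            "group has zero population share; overrepresentation undefined"
        )
        return OverrepresentationResult(
            insurer_id, n_ins, k, ins_share, 0.0, float("nan"), float("nan"), False
        )
    p = stats.binomtest(k, n_ins, pop_share).pvalue
    return OverrepresentationResult(
        insurer_id=insurer_id,
        n_insurer=n_ins,
        n_members_in_insurer=k,
        insurer_share=ins_share,
        population_share=pop_share,
        index=ins_share / pop_share,
        p_value=float(p),
        significant_05=bool(p < 0.05),
    )


def overrepresentation_table(
    panel_year: pd.DataFrame, member: np.ndarray | pd.Series
) -> pd.DataFrame:
    insurers = np.sort(panel_year["insurer_id"].unique())
    rows = [
        overrepresentation_index(panel_year, int(j), member) for j in insurers
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


# --------------------------------------------------------------------- #
# naive insurer-level estimate


def naive_insurer_estimate(residuals: pd.DataFrame) -> pd.DataFrame:
    """Mean overcompensation over ALL enrollees, per insurer.

    This is the intuitive measure a regulator might compute first; it is
    *confounded by the insurer's own efficiency* (an efficient insurer
    has cheap enrollees and hence positive mean overcompensation even
    without any selection), which is why the switcher estimates exist.
    """
    rows = []
    for j, grp in residuals.groupby("insurer_id", observed=True):
        over = grp["overcompensation"].to_numpy()
        n = over.size
        mean = float(over.mean()) if n else float("nan")
        if n >= 2:
            se = float(over.std(ddof=1) / np.sqrt(n))
            test = significance_test(over)
            p = test.p_value
        else:
            se, p = float("nan"), float("nan")
        rows.append(
            {
                "insurer_id": j,
                "n": n,
                "mean_overcompensation": mean,
                "se": se,
                "p_value": p,
                "significant_05": bool(p < 0.05) if p == p else False,
            }
        )
    return pd.DataFrame(rows).set_index("insurer_id")


# --------------------------------------------------------------------- #
# switchers


def identify_switchers(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-person switch status across the two panel years.

    A switcher is present in both years with different insurers.  Persons
    present in only one year (entrants, leavers, deaths) are excluded and
    tallied in ``result.attrs['n_single_year']``.  Duplicate
    (person, year) records are a data error.
    """
    if panel.duplicated(subset=["person_id", "year"]).any():
        raise ValueError("panel contains duplicate (person_id, year) records")
    years = np.sort(panel["year"].unique())
    if len(years) != 2:
        raise ValueError(
            f"switcher analysis needs exactly two panel years, got {list(years)}"
        )
    y1, y2 = int(years[0]), int(years[1])
    a = panel.loc[panel["year"] == y1, ["person_id", "insurer_id"]].set_index(
        "person_id"
    )["insurer_id"]
    b = panel.loc[panel["year"] == y2, ["person_id", "insurer_id"]].set_index(
        "person_id"
    )["insurer_id"]
    common = a.index.intersection(b.index)
    n_single = (len(a) - len(common)) + (len(b) - len(common))
    if n_single:
        logger.info(
            "excluded %d person(s) present in only one year", n_single
        )
    origin = a.loc[common]
    destination = b.loc[common]
    out = pd.DataFrame(
        {
            "person_id": common.to_numpy(),
            "origin": origin.to_numpy(),
            "destination": destination.to_numpy(),
        }
    )
    out["switched"] = out["origin"] != out["destination"]
    out.attrs["n_single_year"] = int(n_single)
    out.attrs["years"] = (y1, y2)
    return out


def switcher_estimates(
    panel: pd.DataFrame,
    residuals_by_year: Mapping[int, pd.DataFrame],
    order: str = "nonswitcher_residual_desc",
) -> pd.DataFrame:
    """Efficiency-unconfounded selection estimates per insurer.

    For insurer X the *inflow* estimate is the mean year-(t-1)
    overcompensation of switchers whose destination is X — expenses
    incurred at their origin insurers — and the *outflow* estimate is the
    mean year-t overcompensation of switchers whose origin is X —
    expenses incurred at their destination insurers.  Estimates with
    fewer than two relevant switchers are marked unavailable.

    ``order`` controls the row ordering:

    * ``"nonswitcher_residual_desc"`` (default): decreasing mean residual
      expenses of year-t non-switchers, the ordering used for published
      insurer tables (the most overcompensated insurer prints last);
    * ``"nonswitcher_overcompensation_desc"``: the mirror-image
      convention;
    * ``"insurer_id"``.
    """
    sw = identify_switchers(panel)
    years = sw.attrs["years"]
    y_prev, y_post = years
    if y_prev not in residuals_by_year or y_post not in residuals_by_year:
        raise ValueError(
            f"residuals_by_year must cover both panel years {years}"
        )
    r_prev = residuals_by_year[y_prev].set_index("person_id")
    r_post = residuals_by_year[y_post].set_index("person_id")

    switchers = sw[sw["switched"]]
    over_prev = r_prev["overcompensation"].reindex(switchers["person_id"]).to_numpy()
    over_post = r_post["overcompensation"].reindex(switchers["person_id"]).to_numpy()

    nonsw = sw.loc[~sw["switched"], ["person_id", "origin"]]
    ns_resid = (
        r_post["residual"]
        .reindex(nonsw["person_id"])
        .groupby(nonsw["origin"].to_numpy())
        .mean()
    )

    insurers = np.sort(
        np.unique(
            np.concatenate(
                [panel["insurer_id"].unique(), sw["origin"].unique()]
            )
        )
    )
    dest = switchers["destination"].to_numpy()
    orig = switchers["origin"].to_numpy()
    rows = []
    for j in insurers:
        row: dict[str, object] = {"insurer_id": int(j)}
        for tag, mask, vals in (
            ("inflow", dest == j, over_prev),
            ("outflow", orig == j, over_post),
        ):
            v = vals[mask]
            v = v[~np.isnan(v)]
            n = v.size
            row[f"n_{tag}"] = n
            if n >= 2:
                test = significance_test(v)
                row[f"{tag}_overcompensation"] = float(v.mean())
                row[f"{tag}_se"] = float(v.std(ddof=1) / np.sqrt(n))
                row[f"{tag}_p_value"] = test.p_value
                row[f"{tag}_significant_05"] = bool(test.p_value < 0.05)
                row[f"{tag}_available"] = True
            else:
                row[f"{tag}_overcompensation"] = float("nan")
                row[f"{tag}_se"] = float("nan")
                row[f"{tag}_p_value"] = float("nan")
                row[f"{tag}_significant_05"] = False
                row[f"{tag}_available"] = False
        row["nonswitcher_mean_residual"] = float(
            ns_resid.get(j, float("nan"))
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if order == "nonswitcher_residual_desc":
        out = out.sort_values(
            "nonswitcher_mean_residual", ascending=False, kind="mergesort"
        )
    elif order == "nonswitcher_overcompensation_desc":
        out = out.sort_values(
            "nonswitcher_mean_residual", ascending=True, kind="mergesort"
        )
    elif order == "insurer_id":
        out = out.sort_values("insurer_id", kind="mergesort")
    else:
        raise ValueError(f"unknown ordering {order!r}")
    out.attrs["n_single_year"] = sw.attrs["n_single_year"]
    return out.reset_index(drop=True)
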