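"""Independent brute-force enumerations of every estimator.

These loop over panel rows one by one with plain Python dictionaries and
only use a numpy mean at the very end (the same averaging primitive the
package uses, so agreement can be asserted bit-exactly).  They share no
code with riskselect.metrics.
"""

from __future__ import annotations

import numpy as np


def residual_lookup(residuals) -> dict:
    """{(person_id, year): (actual, predicted)} from a residual frame."""
    out = {}
    for row in residuals.itertuples(index=False):
        out[(row.person_id, row.year)] = (row.actual, row.predicted)
    return out


def oracle_naive(residuals) -> dict[int, float]:
    """Mean overcompensation over all enrollees, per insurer."""
    per_insurer: dict[int, list[float]] = {}
    for row in residuals.itertuples(index=False):
        per_insurer.setdefault(int(row.insurer_id), []).append(
            row.predicted - row.actual
        )
    return {j: float(np.asarray(v).mean()) for j, v in per_insurer.items()}


def oracle_group(residuals, member) -> tuple[int, float, float, float]:
    """(n, mean overcompensation, predictive ratio, mean actual)."""
    actual, predicted = [], []
    for row, m in zip(residuals.itertuples(index=False), member):
        if m:
            actual.append(row.actual)
            predicted.append(row.predicted)
    a = float(np.asarray(actual).mean())
    p = float(np.asarray(predicted).mean())
    return len(actual), p - a, p / a, a


def oracle_overrepresentation(panel_year, insurer_id, member):
    """(index, insurer share, population share) by explicit counting."""
    n_pop = n_mem = n_ins = n_mem_ins = 0
    for row, m in zip(panel_year.itertuples(index=False), member):
        n_pop += 1
        if m:
            n_mem += 1
        if int(row.insurer_id) == insurer_id:
            n_ins += 1
            if m:
                n_mem_ins += 1
    pop_share = n_mem / n_pop
    ins_share = n_mem_ins / n_ins
    return ins_share / pop_share, ins_share, pop_share


def oracle_switchers(panel, lookup) -> dict[int, dict[str, object]]:
    """Per-insurer inflow/outflow switcher means by full enumeration.

    ``lookup`` maps (person, year) -> (actual, predicted).  Inflow uses
    the earlier year's overcompensation of joiners, outflow the later
    year's overcompensation of leavers.  Row order of the panel decides
    the order in which persons are gathered, matching the package.
    """
    years = sorted(set(int(y) for y in panel["year"]))
    y1, y2 = years
    ins: dict[int, dict[int, int]] = {}
    order: list[int] = []
    for row in panel.itertuples(index=False):
        p = int(row.person_id)
        ins.setdefault(p, {})[int(row.year)] = int(row.insurer_id)
        if int(row.year) == y1 and p not in order:
            order.append(p)
    inflow: dict[int, list[float]] = {}
    outflow: dict[int, list[float]] = {}
    for p in order:
        rec = ins[p]
        if y1 not in rec or y2 not in rec:
            continue
        if rec[y1] == rec[y2]:
            continue
        a_prev, pr_prev = lookup[(p, y1)]
        a_post, pr_post = lookup[(p, y2)]
        inflow.setdefault(rec[y2], []).append(pr_prev - a_prev)
        outflow.setdefault(rec[y1], []).append(pr_post - a_post)
    out: dict[int, dict[str, object]] = {}
    all_insurers = sorted(
        set(list(inflow) + list(outflow) + [int(j) for j in panel["insurer_id"]])
    )
    for j in all_insurers:
        v_in = inflow.get(j, [])
        v_out = outflow.get(j, [])
        out[j] = {
            "n_inflow": len(v_in),
            "inflow": float(np.asarray(v_in).mean()) if len(v_in) >= 2 else None,
            "n_outflow": len(v_out),
            "outflow": float(np.asarray(v_out).mean()) if len(v_out) >= 2 else None,
        }
    return out
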