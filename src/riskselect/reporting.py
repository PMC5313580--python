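"""Report rendering and run manifests.

Two table styles are supported, mirroring the layouts regulators publish:

* ``table2`` — one row per selected group: population share, mean over-
  or undercompensation, predictive ratio, reduction versus no
  equalization, significance stars;
* ``table4`` — one row per insurer: inflow (new enrollees, pre-switch
  year) and outflow (disenrollees, post-switch year) mean
  overcompensation with stars, ordered by the non-switcher residual key.

CSV output keeps full numeric precision (reports re-parse to the exact
in-memory values); display rounding — euros to integers, predictive
ratios to two decimals, reductions as signed percentages — applies to
the Markdown rendering only.  Unavailable estimates render as "-" with
the count still shown.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .config import MarketConfig

_STYLES = ("table2", "table4")


def render_table(rows: pd.DataFrame, style: str, fmt: str = "csv") -> str:
    """Render a compensation (table2) or switcher (table4) table.

    ``fmt="csv"`` emits full precision; ``fmt="markdown"`` applies the
    display rounding conventions.
    """
    if style not in _STYLES:
        raise ValueError(f"unknown table style {style!r}; expected {_STYLES}")
    if rows.empty:
        raise ValueError("cannot render an empty table")
    if fmt == "csv":
        return rows.to_csv(index=False)
    if fmt != "markdown":
        raise ValueError(f"unknown format {fmt!r}")
    if style == "table2":
        return _markdown_table2(rows)
    return _markdown_table4(rows)


def _stars(row: Mapping[str, Any], key05: str, key01: str | None = None) -> str:
    if key01 is not None and row.get(key01, False):
        return "**"
    return "*" if row.get(key05, False) else ""


def _markdown_table2(rows: pd.DataFrame) -> str:
    header = (
        "| Selected group | % of population | Over/undercompensation | "
        "Predictive ratio | Reduction vs no equalization |\n"
        "|---|---|---|---|---|"
    )
    lines = [header]
    for _, r in rows.iterrows():
        stars = _stars(r, "significant_05", "significant_01")
        pr = "-" if pd.isna(r["predictive_ratio"]) else f"{r['predictive_ratio']:.2f}"
        red = (
            "-"
            if pd.isna(r["reduction_vs_no_equalization"])
            else f"−{100 * r['reduction_vs_no_equalization']:.0f} %"
        )
        over = r["mean_overcompensation"]
        lines.append(
            f"| {r['group_label']} | {100 * r['population_share']:.1f} % | "
            f"{over:+.0f}{stars} | {pr} | {red} |"
        )
    return "\n".join(lines) + "\n"


def _fmt_estimate(row: Mapping[str, Any], tag: str) -> str:
    if not row.get(f"{tag}_available", True) or pd.isna(
        row[f"{tag}_overcompensation"]
    ):
        return f"- (n={int(row[f'n_{tag}'])})"
    stars = _stars(row, f"{tag}_significant_05")
    return f"{row[f'{tag}_overcompensation']:+.0f}{stars}"

def _markdown_table4(rows: pd.DataFrame) -> str:
    header = (
        "| Insurer | New enrollees: overcompensation, pre-switch year | "
        "Disenrollees: overcompensation, post-switch year |\n|---|---|---|"
    )
    lines = [header]
    for _, r in rows.iterrows():
        lines.append(
            f"| {int(r['insurer_id'])} | {_fmt_estimate(r, 'inflow')} | "
            f"{_fmt_estimate(r, 'outflow')} |"
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------- #
# manifest


@dataclass
class RunManifest:
    """Traceability record written next to every report bundle."""

    config_hash: str
    seed: int
    package_version: str = __version__
    created_utc: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    outputs: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def write_bundle(
    bundle: Mapping[str, Any], out_dir: str, emit_truth: bool = False
) -> RunManifest:
    """Write a pipeline bundle as CSV/Markdown/JSON files plus manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    config: MarketConfig = bundle["config"]
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)

    def _write(name: str, text: str) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        manifest.outputs[name] = path

    panel: pd.DataFrame = bundle["panel"]
    cols = [c for c in panel.columns if emit_truth or c != "unpriced_effect"]
    _write("panel.csv", panel[cols].to_csv(index=False))
    bundle["ground_truth"].to_json(os.path.join(out_dir, "truth.json"))
    manifest.outputs["truth.json"] = os.path.join(out_dir, "truth.json")
    for year, model in bundle["models"].items():
        name = f"model_{year}.json"
        model.to_json(os.path.join(out_dir, name))
        manifest.outputs[name] = os.path.join(out_dir, name)
    for year, res in bundle["residuals"].items():
        _write(f"residuals_{year}.csv", res.to_csv(index=False))
    _write("groups.csv", render_table(bundle["group_table"], "table2", "csv"))
    _write("groups.md", render_table(bundle["group_table"], "table2", "markdown"))
    _write(
        "switchers.csv", render_table(bundle["switcher_table"], "table4", "csv")
    )
    _write(
        "switchers.md",
        render_table(bundle["switcher_table"], "table4", "markdown"),
    )
    _write("naive.csv", bundle["naive_table"].to_csv())
    if bundle.get("overrepresentation_table") is not None:
        _write(
            "overrepresentation.csv",
            bundle["overrepresentation_table"].to_csv(index=False),
        )
    manifest.exclusions["single_year_persons"] = int(
        bundle["switcher_table"].attrs.get("n_single_year", 0)
    )
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    manifest.outputs["manifest.json"] = os.path.join(out_dir, "manifest.json")
    return manifest
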