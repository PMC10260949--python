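"""Delimited-text report tables for a batch of scenario runs.

Shapes mirror the study's reporting surface: a price table (scenario x
pass-through -> new SSB price and % change), an intake-change table (one
row per stratum), DPP/LYG totals per scenario x pass-through with
optional 95% UIs, DPP as % of baseline deaths by age group, and DPP/LYG
by IMD quintile. Percentages are rounded to integers and prices to two
decimals in the display columns; full-precision columns are kept
alongside so re-runs byte-reproduce and downstream consumers need not
re-derive anything.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import ImpactResults

_FLOAT_FMT = "%.10g"


def price_table(results: list[ImpactResults], baseline_price: float) -> pd.DataFrame:
    rows = []
    for r in results:
        p = r.point
        rows.append(
            {
                "scenario": p.label,
                "pass_through": p.pass_through,
                "cost_change_gbp_per_l": p.cost_change,
                "new_price_gbp_per_l": round(
                    baseline_price * (1 + p.consumer_price_change), 2
                ),
                "price_change_pct": round(100 * p.consumer_price_change),
            }
        )
    return pd.DataFrame(rows)


def intake_table(result: ImpactResults) -> pd.DataFrame:
    cols = [
        "age_group",
        "sex",
        "imd_quintile",
        "relative_change",
        "absolute_change",
        "servings_change",
    ]
    return result.per_stratum[cols].copy()


def results_table(results: list[ImpactResults]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "scenario": r.point.label,
            "pass_through": r.point.pass_through,
            "dpp": r.dpp,
            "lyg": r.lyg,
            "overall_intake_change_pct": round(100 * r.overall_intake_change),
        }
        if r.psa is not None:
            dm, dl, du = r.psa.dpp
            lm, ll, lu = r.psa.lyg
            row.update(
                dpp_mean=dm, dpp_lower95=dl, dpp_upper95=du,
                lyg_mean=lm, lyg_lower95=ll, lyg_upper95=lu,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def age_group_table(results: list[ImpactResults]) -> pd.DataFrame:
    frames = []
    for r in results:
        g = r.by_age_group()
        g.insert(0, "scenario", r.point.label)
        g.insert(1, "pass_through", r.point.pass_through)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def quintile_table(results: list[ImpactResults]) -> pd.DataFrame:
    frames = []
    for r in results:
        g = r.by_quintile()
        g.insert(0, "scenario", r.point.label)
        g.insert(1, "pass_through", r.point.pass_through)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def write_reports(
    results: list[ImpactResults],
    out_dir: str | Path,
    baseline_price: float,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write all report tables to ``out_dir``; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "price_table": price_table(results, baseline_price),
        "results_by_scenario": results_table(results),
        "dpp_by_age_group": age_group_table(results),
        "dpp_lyg_by_quintile": quintile_table(results),
        "intake_changes": intake_table(results[0]),
    }
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths[name] = path
    if manifest is not None:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = path
    return paths
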