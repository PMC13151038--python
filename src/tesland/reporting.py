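"""Scenario comparison tables and spatiotemporal map exports.

The comparison report mirrors the standard accounting of a design-case
study: annualized private cost, additional averted mortalities relative to
the technology-only baseline (with 95% CIs), carbon uptake, the biogenic
share of that uptake, and total social benefits.  Derived quantities (the
best/worst averted-mortality ratio and the fraction of health benefit lost
to carbon-only siting) are always recomputed from the per-scenario entries.
Every row satisfies the decomposition identity

    social benefits = SCC x CO2 uptake + VSL x averted mortalities

because both sides are computed from the same ledgers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .landscape import ReceptorGrid, grid_to_geojson
from .optimizer import DesignSolution, ScenarioSummary


def decomposition_identity(
    carbon_uptake_mt: float,
    averted_mortalities: float,
    scc_usd_per_tonne: float = 56.2,
    vsl_musd: float = 8.7,
) -> float:
    """Total social benefits in million USD/yr from its two components.

    ``carbon_uptake_mt`` is annual CO2 uptake in megatonnes;
    ``averted_mortalities`` annual incidences.  The identity is exact by
    construction of the valuation model (both benefit streams are linear).
    """
    return scc_usd_per_tonne * carbon_uptake_mt + vsl_musd * averted_mortalities


def _fmt_money_millions(usd: float) -> str:
    return f"{usd / 1e6:.0f}"


def _fmt_mortalities(x: float) -> str:
    return f"{x:.2f}" if abs(x) < 1 else f"{x:.1f}"


def _fmt_ci(ci: tuple[float, float, float] | None, fmt) -> str:
    if ci is None:
        return ""
    lo, _, hi = ci
    return f"({fmt(lo)}, {fmt(hi)})"


@dataclass
class ComparisonReport:
    """Comparison-table data plus recomputed cross-scenario quantities."""

    table: pd.DataFrame  # raw values, one column per scenario
    formatted: pd.DataFrame  # display strings
    best_worst_ratio: float
    pct_health_benefit_lost: float

    def to_csv(self, path) -> None:
        self.formatted.to_csv(path)

    def to_json(self, path=None) -> str:
        payload = {
            "scenarios": json.loads(self.table.to_json()),
            "best_worst_ratio": self.best_worst_ratio,
            "pct_health_benefit_lost": self.pct_health_benefit_lost,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def render_comparison(summaries: dict[str, ScenarioSummary]) -> ComparisonReport:
    """Build the cross-scenario comparison from solved-scenario summaries.

    Requires the technology-only scenario as the baseline column.  Derived
    quantities are recomputed here from the mortality column, never stored.
    """
    if "tech_only" not in summaries:
        raise ValidationError("comparison needs the 'tech_only' baseline scenario")
    rows = {}
    for name, s in summaries.items():
        rows[name] = {
            "private_cost_musd": s.private_cost_annual_usd / 1e6,
            "additional_averted_mortalities": s.additional_averted_annual,
            "carbon_uptake_mt": s.carbon_uptake_annual_t / 1e6,
            "biogenic_share_pct": s.biogenic_share_pct,
            "total_social_benefits_musd": s.social_benefit_annual_usd / 1e6,
            "planted_receptors": s.planted_count,
            "averted_ci_lo": s.averted_ci[0] if s.averted_ci else np.nan,
            "averted_ci_hi": s.averted_ci[2] if s.averted_ci else np.nan,
            "social_ci_lo_musd": s.social_ci[0] / 1e6 if s.social_ci else np.nan,
            "social_ci_hi_musd": s.social_ci[2] / 1e6 if s.social_ci else np.nan,
        }
    table = pd.DataFrame(rows)

    formatted = pd.DataFrame(
        {
            name: {
                "private costs [USD]": f"{r['private_cost_musd']:.0f} million",
                "additional averted mortalities": _fmt_mortalities(
                    r["additional_averted_mortalities"]
                )
                + (
                    f" ({_fmt_mortalities(r['averted_ci_lo'])}, {_fmt_mortalities(r['averted_ci_hi'])})"
                    if np.isfinite(r["averted_ci_lo"])
                    else ""
                ),
                "carbon uptake [Mt]": f"{r['carbon_uptake_mt']:.2f}",
                "biogenic sequestration [%]": f"{r['biogenic_share_pct']:.1f}",
                "total social benefits (million USD)": f"{r['total_social_benefits_musd']:.0f}"
                + (
                    f" ({r['social_ci_lo_musd']:.0f}, {r['social_ci_hi_musd']:.0f})"
                    if np.isfinite(r["social_ci_lo_musd"])
                    else ""
                ),
            }
            for name, r in table.to_dict().items()
        }
    )

    mort = table.loc["additional_averted_mortalities"]
    ratio = np.nan
    pct_lost = np.nan
    if "tes_plus_budgetmatch" in table.columns and "co2_minus" in table.columns:
        best = float(mort["tes_plus_budgetmatch"])
        worst = float(mort["co2_minus"])
        if worst > 0:
            ratio = best / worst
        pct_lost = (1.0 - worst / best) * 100.0 if best > 0 else np.nan
    return ComparisonReport(
        table=table,
        formatted=formatted,
        best_worst_ratio=float(ratio),
        pct_health_benefit_lost=float(pct_lost),
    )


def export_maps(
    sol: DesignSolution, grid: ReceptorGrid, csv_path=None, geojson_path=None
) -> tuple[pd.DataFrame, dict]:
    """Planting-year map of one solution.

    One record per *available* receptor, with the planting year or null if
    the optimizer left it unplanted; deterministic (y, x) ordering.  Earlier
    years mark higher-priority locations.
    """
    unc = np.where(grid.unconstrained)[0]
    plant_year = np.full(grid.n_receptors, np.nan)
    for k, idx in enumerate(unc):
        if sol.planted_year[k] >= 0:
            plant_year[idx] = sol.planted_year[k]
    df = pd.DataFrame(
        {
            "receptor_id": grid.receptor_id[unc],
            "x_km": grid.x_km[unc],
            "y_km": grid.y_km[unc],
            "plant_year": pd.array(
                [
                    int(plant_year[i]) if np.isfinite(plant_year[i]) else None
                    for i in unc
                ],
                dtype="Int64",  # nullable: unselected receptors stay blank in CSV
            ),
        }
    )
    sub_grid_props = {"plant_year": plant_year}
    geo = grid_to_geojson(grid, sub_grid_props)
    geo["features"] = [f for f in geo["features"] if f["properties"]["unconstrained"]]
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if geojson_path is not None:
        Path(geojson_path).write_text(json.dumps(geo))
    return df, geo


def plot_planting_map(sol: DesignSolution, grid: ReceptorGrid, ax=None):
    """Year-coded planting map (optional matplotlib hook)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    unc = np.where(grid.unconstrained)[0]
    planted = sol.planted_year >= 0
    ax.scatter(
        grid.x_km[unc[~planted]], grid.y_km[unc[~planted]],
        marker="s", facecolors="none", edgecolors="k", s=18, linewidths=0.4,
        label="available, unselected",
    )
    if planted.any():
        sc = ax.scatter(
            grid.x_km[unc[planted]], grid.y_km[unc[planted]],
            c=sol.planted_year[planted], cmap="autumn", marker="s", s=22,
            label="planted",
        )
        plt.colorbar(sc, ax=ax, label="planting year")
    ax.plot(0, 0, "k^", markersize=9, label="source")
    ax.set_xlabel("x [km]")
    ax.set_ylabel("y [km]")
    ax.set_title(f"land-use change, scenario '{sol.spec.name}'")
    ax.legend(loc="upper right", fontsize=7)
    return ax
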