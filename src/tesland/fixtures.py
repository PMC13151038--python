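"""Synthetic input bundles with the structure of a real case study.

The generator emulates the spatial statistics the design framework feeds on
without reproducing any particular county: spatially clustered population
(urban bumps on a lognormal rural background), developed land correlated
with population so dense cells tend to fail the availability rule, a river
band of water-dominated cells, ozone concentration deltas driven by the
availability of convertible land, PM2.5 deltas following a distance-decaying
wind-skewed plume kernel centered on the source, and growth tables with a
young-stand net-carbon-emission dip followed by a sigmoidal rise.  Facility
and technology parameters are scaled to the generated landscape so that the
canonical scenario suite exhibits the qualitative regimes of interest:
capture-only neutrality in early years, a biogenic crossover, staggered
planting under a binding budget, and population-seeking planting once
health benefits are monetized.

All randomness is governed by a single seed, and bundles are written to the
exact public file formats the readers consume, so every end-to-end test
also exercises I/O.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbon as carbon_mod
from . import health as health_mod
from .errors import ValidationError
from .growth import GrowthSeries, fit_growth_curve
from .landscape import (
    DeltaFields,
    PopulationLayer,
    ReceptorGrid,
    compute_constraint_mask,
    read_landscape,
    write_landscape,
)
from .optimizer import FacilityEmissions, TechnologyUnit, TESProblem

# magnitudes of the synthetic dispersion deltas (full afforestation)
_PM25_DC_PEAK = 0.9  # ug/m3 at the source
_O3_DC_PER_CONV = 2.0  # ppb per unit convertible fraction
_PM25_DEP_PEAK = 5.0  # t/yr per receptor at the source, fully convertible
_NOX_DEP_PEAK = 6.0  # t/yr per receptor, fully convertible
_PLUME_LENGTH_KM = 18.0
_PLUME_SKEW = 0.7

# technology cost assumptions (USD per tonne removed)
_COST_SCR = 1600.0
_COST_BHF = 900.0
_COST_CCS = 60.0


@dataclass
class FixtureSpec:
    """Knobs of the synthetic landscape generator."""

    nx: int = 41
    ny: int = 41
    spacing_km: float = 2.5
    seed: int = 0
    urban_centers: int = 3
    wind_bearing_deg: float = 22.5  # dominant plume direction, degrees from north
    fraction_constrained_target: float = 0.12
    horizon: int = 60

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValidationError("grid must be at least 2 x 2")
        if not (0.0 < self.fraction_constrained_target < 1.0):
            raise ValidationError("fraction_constrained_target must be in (0, 1)")
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")


def preset_spec(size: str, seed: int = 0) -> FixtureSpec:
    """Named sizes: ``small`` for test suites, ``full`` for the 41x41 case."""
    if size == "small":
        return FixtureSpec(nx=10, ny=10, seed=seed, urban_centers=2, horizon=30)
    if size == "full":
        return FixtureSpec(seed=seed)
    raise ValidationError(f"unknown preset '{size}' (use 'small' or 'full')")


def plume_kernel(r_km, bearing_deg, wind_bearing_deg: float = 22.5):
    """Distance-decaying, wind-skewed plume shape in [0, 1+skew].

    Strictly decreasing in distance along any fixed bearing; largest along
    the dominant wind direction.
    """
    r_km = np.asarray(r_km, dtype=float)
    rel = np.deg2rad(np.asarray(bearing_deg, dtype=float) - wind_bearing_deg)
    return np.exp(-r_km / _PLUME_LENGTH_KM) * (1.0 + _PLUME_SKEW * np.cos(rel))


def _growth_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic 80-year stand trajectories in native units.

    Crown cover saturates from bare ground; the live-carbon annual change
    dips negative for young stands (respiration exceeds fixation) before a
    sigmoidal rise toward a peak near the end of the simulated window.
    """
    ages = np.arange(0.0, 81.0, 2.0)
    crown = 85.0 * (1.0 - np.exp(-ages / 14.0))  # percent cover
    # zero at planting, respiration dip bottoming near age 5 with net
    # sequestration from the mid-teens, sigmoidal rise toward the peak rate
    logistic = 1.0 / (1.0 + np.exp(-(ages - 30.0) / 11.0))
    dip = 0.22 * (ages / 5.0) * np.exp(1.0 - ages / 5.0)
    carb = 3.0 * (logistic - logistic[0] - dip)
    return (
        pd.DataFrame({"age_years": ages, "value": crown}),
        pd.DataFrame({"age_years": ages, "value": carb}),
    )


def _fast_growth_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compressed trajectories for tiny instances with 2-3 year horizons."""
    ages = np.arange(0.0, 9.0, 1.0)
    crown = 1.0 - np.exp(-ages / 1.2)
    carb = 1.0 / (1.0 + np.exp(-(ages - 1.5) / 0.8)) - 0.25 * np.exp(-ages / 0.6)
    return (
        pd.DataFrame({"age_years": ages, "value": crown}),
        pd.DataFrame({"age_years": ages, "value": carb}),
    )


def _synthesize_landscape(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    nx, ny, d = spec.nx, spec.ny, spec.spacing_km
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))  # row-major by y then x
    x = ((ix - (nx - 1) / 2.0) * d).ravel()
    y = ((iy - (ny - 1) / 2.0) * d).ravel()
    n = x.size
    r = np.hypot(x, y)
    bearing = np.degrees(np.arctan2(x, y))  # 0 = north, 90 = east
    cell_km2 = d * d
    half = (nx - 1) / 2.0 * d

    # population: lognormal rural background plus Gaussian urban bumps
    rural = rng.lognormal(mean=np.log(25.0), sigma=0.6, size=n)  # persons/km2
    density = rural.copy()
    for _ in range(spec.urban_centers):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.45) * 2 * half
        cx, cy = rad * np.sin(ang), rad * np.cos(ang)
        amp = rng.uniform(900.0, 2600.0)
        sig = rng.uniform(0.06, 0.12) * 2 * half
        density += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sig**2))
    population = np.round(density * cell_km2)

    y0 = np.clip(rng.normal(0.0088, 0.0004, size=n), 0.006, 0.012)

    # river band: a meandering line crossing the domain
    river_dist = np.abs(y - 0.35 * x - 0.25 * half * np.sin(x / (0.3 * half + 1e-9)) + 0.3 * half)
    river = river_dist < 0.8 * d

    # designate exactly the target number of constrained receptors:
    # the densest cells plus the river core
    n_con = int(round(spec.fraction_constrained_target * n))
    score = population.astype(float).copy()
    score[river] += 1e12  # river cells are constrained first
    con_idx = np.argsort(score)[::-1][:n_con]
    constrained = np.zeros(n, dtype=bool)
    constrained[con_idx] = True

    developed = np.empty(n)
    water = np.empty(n)
    pop_norm = population / max(population.max(), 1.0)
    for k in range(n):
        if constrained[k]:
            if river[k]:
                water[k] = rng.uniform(0.45, 0.65)
                developed[k] = rng.uniform(0.10, 0.25)
            else:
                developed[k] = rng.uniform(0.55, 0.80)
                water[k] = rng.uniform(0.0, 0.05)
        else:
            developed[k] = min(0.03 + 0.30 * pop_norm[k] * rng.uniform(0.5, 1.0), 0.38)
            water[k] = rng.uniform(0.0, 0.06)
            overflow = developed[k] + water[k] - 0.45
            if overflow > 0:
                water[k] = max(water[k] - overflow, 0.0)
    rem = 1.0 - developed - water
    mix = rng.dirichlet((2.0, 4.0, 0.8), size=n)  # forest, agri/grass, barren
    forest = rem * mix[:, 0]
    agri = rem * mix[:, 1]
    barren = rem * mix[:, 2]

    grid = ReceptorGrid(
        receptor_id=np.arange(n),
        x_km=x,
        y_km=y,
        spacing_km=d,
        landcover={
            "developed": developed,
            "water": water,
            "forest": forest,
            "agri_grass": agri,
            "barren": barren,
        },
    )
    compute_constraint_mask(grid)

    conv = agri + barren  # convertible fraction
    avail = grid.unconstrained.astype(float)
    plume = plume_kernel(r, bearing, spec.wind_bearing_deg)
    fields = DeltaFields(
        dC={
            "pm25": _PM25_DC_PEAK / (1 + _PLUME_SKEW) * plume * avail,
            "o3": _O3_DC_PER_CONV * conv * avail,
        },
        ddep={
            "nox": _NOX_DEP_PEAK * conv * (0.6 + 0.4 * plume / (1 + _PLUME_SKEW)) * avail,
            "pm25": _PM25_DEP_PEAK / (1 + _PLUME_SKEW) * plume * conv * avail,
        },
    )
    pop_layer = PopulationLayer(population=population, y0=y0)
    return grid, fields, pop_layer


def _facility_config(spec: FixtureSpec, grid: ReceptorGrid, fields: DeltaFields) -> dict:
    """Scale facility parameters to the generated landscape.

    The CO2 emission rate is set so that full-maturity biogenic
    sequestration of roughly half the unconstrained area covers it; capture
    capacity carries 30% headroom to absorb the young-stand respiration
    debit.  NOx/PM2.5 uptake targets are an order of magnitude above the
    full ecological deposition potential, so technologies retain most of the
    load (the dry-deposition pathway is physically small next to stack
    controls).  The annual planting budget is 5% of the estimated
    business-as-usual operating cost, which forces staggered planting.
    """
    R = carbon_mod.additionality_fraction(grid)
    unc = grid.unconstrained
    chi_max = carbon_mod.DEFAULT_VC * R * grid.area_ha * float(np.sum(unc))
    co2 = round(0.55 * chi_max)
    dep_nox = float(np.sum(fields.ddep["nox"]))
    dep_pm = float(np.sum(fields.ddep["pm25"]))
    target_nox = round(12.0 * dep_nox)
    target_pm = round(15.0 * dep_pm)
    bau_cost = co2 * _COST_CCS + target_nox * _COST_SCR + target_pm * _COST_BHF
    return {
        "horizon": spec.horizon,
        "annual_luc_budget": round(0.05 * bau_cost),
        "plant_cost_per_acre": 376.0,
        "vc_tonnes_per_ha_yr": carbon_mod.DEFAULT_VC,
        "scc_usd_per_tonne": carbon_mod.DEFAULT_SCC,
        "vsl_usd": health_mod.DEFAULT_VSL,
        "vsl_weibull_shape": health_mod.DEFAULT_VSL_WEIBULL_SHAPE,
        "impact_functions": [
            {"pollutant": p, "beta_mean": m, "beta_sd": sd, "endpoint": "Mortality, All Causes"}
            for p, (m, sd) in health_mod.DEFAULT_HIFS.items()
        ],
        "emissions": {"nox": round(target_nox / 0.9), "pm25": round(target_pm / 0.9), "co2": co2},
        "uptake_targets": {"nox": target_nox, "pm25": target_pm},
        "technologies": [
            {"name": "SCR", "pollutant": "nox", "max_uptake": round(1.05 * target_nox),
             "cost_variable": _COST_SCR, "cost_fixed": 0.0},
            {"name": "BHF", "pollutant": "pm25", "max_uptake": round(1.05 * target_pm),
             "cost_variable": _COST_BHF, "cost_fixed": 0.0},
            {"name": "CCS", "pollutant": "co2", "max_uptake": round(1.30 * co2),
             "cost_variable": _COST_CCS, "cost_fixed": 0.0},
        ],
    }


def generate_landscape(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write a complete input bundle (grid, fields, growth tables, config).

    Deterministic: the same spec (including seed) produces byte-identical
    files.  Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid, fields, pop = _synthesize_landscape(spec)
    paths = {
        "grid": outdir / "grid.csv",
        "fields": outdir / "fields.csv",
        "crown_cover": outdir / "crown_cover.csv",
        "live_carbon": outdir / "live_carbon.csv",
        "config": outdir / "config.json",
    }
    write_landscape(grid, fields, pop, paths["grid"], paths["fields"])
    crown_df, carb_df = _growth_tables()
    crown_df.to_csv(paths["crown_cover"], index=False)
    carb_df.to_csv(paths["live_carbon"], index=False)
    config = _facility_config(spec, grid, fields)
    paths["config"].write_text(json.dumps(config, indent=1, sort_keys=True))
    return paths


@dataclass
class FixtureBundle:
    """A loaded input bundle ready for optimization."""

    problem: TESProblem
    horizon: int
    annual_luc_budget: float
    plant_cost_per_acre: float
    config: dict


def load_bundle(outdir) -> FixtureBundle:
    """Read a bundle from disk through the public readers and fitters."""
    outdir = Path(outdir)
    grid, fields, pop = read_landscape(outdir / "grid.csv", outdir / "fields.csv")
    config = json.loads((outdir / "config.json").read_text())

    def _fit(path, attribute):
        df = pd.read_csv(path)
        return fit_growth_curve(
            GrowthSeries(attribute, df["age_years"].to_numpy(), df["value"].to_numpy())
        )

    crown = _fit(outdir / "crown_cover.csv", "crown_cover")
    carb = _fit(outdir / "live_carbon.csv", "live_carbon")
    R = carbon_mod.additionality_fraction(grid)
    problem = TESProblem(
        grid=grid,
        fields=fields,
        population=pop,
        crown_curve=crown,
        carbon_model=carbon_mod.CarbonModel(
            vc=config["vc_tonnes_per_ha_yr"],
            r=R,
            area_ha=np.full(grid.n_receptors, grid.area_ha),
            carbon_curve=carb,
        ),
        hifs=[
            health_mod.HealthImpactFunction(
                f["pollutant"], f["beta_mean"], f["beta_sd"], f["endpoint"]
            )
            for f in config["impact_functions"]
        ],
        valuation=health_mod.IncidenceValuation.from_mean(
            config["vsl_usd"], config["vsl_weibull_shape"]
        ),
        scc=carbon_mod.SocialCostCarbon(config["scc_usd_per_tonne"]),
        technologies=[
            TechnologyUnit(
                t["name"], t["pollutant"], t["max_uptake"], t["cost_variable"], t["cost_fixed"]
            )
            for t in config["technologies"]
        ],
        emissions=FacilityEmissions(
            emissions={k: float(v) for k, v in config["emissions"].items()},
            uptake_targets={k: float(v) for k, v in config["uptake_targets"].items()},
        ),
    )
    return FixtureBundle(
        problem=problem,
        horizon=int(config["horizon"]),
        annual_luc_budget=float(config["annual_luc_budget"]),
        plant_cost_per_acre=float(config["plant_cost_per_acre"]),
        config=config,
    )


def tiny_instance(seed: int = 0, outdir=None, horizon: int = 3) -> FixtureBundle:
    """A miniature bundle small enough for exhaustive enumeration.

    A 2 x 2 grid with two unconstrained receptors and a 3-year horizon gives
    at most 6 planting binaries (64 patterns).  Growth is compressed so that
    planting has consequences within the horizon, and the budget admits one
    planting per year.  The bundle is written to disk and read back through
    the public formats.
    """
    if outdir is None:
        outdir = tempfile.mkdtemp(prefix="tesland-tiny-")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    d = 2.5
    x = np.array([-d / 2, d / 2, -d / 2, d / 2])
    y = np.array([-d / 2, -d / 2, d / 2, d / 2])
    developed = np.array([0.70, 0.10, 0.60, 0.05])
    water = np.array([0.02, 0.03, 0.02, 0.02])
    rem = 1.0 - developed - water
    forest = rem * np.array([0.3, 0.25, 0.3, 0.40])
    agri = rem * np.array([0.6, 0.65, 0.6, 0.50])
    barren = rem - forest - agri
    grid = ReceptorGrid(
        receptor_id=np.arange(4),
        x_km=x,
        y_km=y,
        spacing_km=d,
        landcover={
            "developed": developed,
            "water": water,
            "forest": forest,
            "agri_grass": agri,
            "barren": barren,
        },
    )
    compute_constraint_mask(grid)
    avail = grid.unconstrained.astype(float)
    pop = PopulationLayer(
        population=np.round(rng.uniform(500, 20000, size=4)),
        y0=np.full(4, 0.0088),
    )
    fields = DeltaFields(
        dC={
            "pm25": np.array([0.0, 0.5, 0.0, 0.3]) * avail,
            "o3": np.array([0.0, 1.2, 0.0, 0.9]) * avail,
        },
        ddep={
            "nox": np.array([0.0, 2.0, 0.0, 1.5]) * avail,
            "pm25": np.array([0.0, 0.8, 0.0, 0.6]) * avail,
        },
    )
    write_landscape(grid, fields, pop, outdir / "grid.csv", outdir / "fields.csv")
    crown_df, carb_df = _fast_growth_tables()
    crown_df.to_csv(outdir / "crown_cover.csv", index=False)
    carb_df.to_csv(outdir / "live_carbon.csv", index=False)

    R = carbon_mod.additionality_fraction(grid)
    area = grid.area_ha
    full_rate = carbon_mod.DEFAULT_VC * R * area  # one mature receptor, t/yr
    co2 = round(0.8 * full_rate)
    conv = (agri + barren) * area
    plant_costs = 376.0 * 2.471053814671653 * conv[grid.unconstrained]
    config = {
        "horizon": horizon,
        "annual_luc_budget": round(1.05 * float(np.max(plant_costs))),
        "plant_cost_per_acre": 376.0,
        "vc_tonnes_per_ha_yr": carbon_mod.DEFAULT_VC,
        "scc_usd_per_tonne": carbon_mod.DEFAULT_SCC,
        "vsl_usd": health_mod.DEFAULT_VSL,
        "vsl_weibull_shape": health_mod.DEFAULT_VSL_WEIBULL_SHAPE,
        "impact_functions": [
            {"pollutant": p, "beta_mean": m, "beta_sd": sd, "endpoint": "Mortality, All Causes"}
            for p, (m, sd) in health_mod.DEFAULT_HIFS.items()
        ],
        "emissions": {"nox": 1000.0, "pm25": 200.0, "co2": co2},
        "uptake_targets": {"nox": 900.0, "pm25": 180.0},
        "technologies": [
            {"name": "SCR", "pollutant": "nox", "max_uptake": 950.0,
             "cost_variable": _COST_SCR, "cost_fixed": 0.0},
            {"name": "BHF", "pollutant": "pm25", "max_uptake": 190.0,
             "cost_variable": _COST_BHF, "cost_fixed": 0.0},
            {"name": "CCS", "pollutant": "co2", "max_uptake": round(1.4 * co2),
             "cost_variable": _COST_CCS, "cost_fixed": 0.0},
        ],
    }
    (outdir / "config.json").write_text(json.dumps(config, indent=1, sort_keys=True))
    return load_bundle(outdir)
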