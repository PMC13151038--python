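"""Receptor-grid data model and I/O.

The spatial domain is a complete rectangular grid of receptors centered on an
industrial point source (source at the origin, x east, y north).  Each
receptor carries land-cover fractions, exposed population, a baseline
mortality incidence rate, and precomputed dispersion deltas: the
concentration reduction and dry-deposition increment each pollutant would see
if the receptor's convertible land were fully afforested.  Those deltas come
from an external dispersion model run under two static land-cover states
(current vs. fully afforested); this package consumes them as tabular fields
and never re-simulates dispersion.

A receptor is *available* for planting ("unconstrained") when less than half
of its area is developed land or open water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, StructureError, ValidationError

LANDCOVER_CLASSES = ("developed", "water", "forest", "agri_grass", "barren")

#: columns of the grid table, in canonical order
GRID_COLUMNS = (
    "receptor_id",
    "x_km",
    "y_km",
    "f_developed",
    "f_water",
    "f_forest",
    "f_agri_grass",
    "f_barren",
    "population",
    "y0_mortality",
)

#: columns of the dispersion-delta table
FIELD_COLUMNS = ("receptor_id", "dC_pm25", "dC_o3", "ddep_nox_t", "ddep_pm25_t")

_FRACTION_TOL = 1e-9


@dataclass
class ReceptorGrid:
    """Rectangular receptor grid with land cover.

    Attributes
    ----------
    receptor_id : integer index per receptor (row order is canonical (y, x)).
    x_km, y_km : cell-center coordinates, source at (0, 0).
    spacing_km : inter-node distance.
    landcover : mapping class name -> fraction array; fractions sum to 1.
    unconstrained : availability mask, ``developed + water < 0.5``.
    """

    receptor_id: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    spacing_km: float
    landcover: dict[str, np.ndarray]
    unconstrained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.receptor_id = np.asarray(self.receptor_id, dtype=np.int64)
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.landcover = {k: np.asarray(v, dtype=float) for k, v in self.landcover.items()}
        self._validate()
        if self.unconstrained is None:
            self.unconstrained = compute_constraint_mask(self)
        else:
            self.unconstrained = np.asarray(self.unconstrained, dtype=bool)

    # -- geometry -----------------------------------------------------------

    @property
    def n_receptors(self) -> int:
        return self.receptor_id.size

    @property
    def area_ha(self) -> float:
        """Cell area in hectares (spacing_km^2 * 100)."""
        return self.spacing_km**2 * 100.0

    @property
    def shape(self) -> tuple[int, int]:
        """(n_y, n_x) of the rectangular grid."""
        ys = np.unique(self.y_km)
        xs = np.unique(self.x_km)
        return ys.size, xs.size

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        n = self.receptor_id.size
        for name in ("x_km", "y_km"):
            if getattr(self, name).size != n:
                raise StructureError(f"{name} has length {getattr(self, name).size}, expected {n}")
        missing = [c for c in LANDCOVER_CLASSES if c not in self.landcover]
        if missing:
            raise SchemaError(f"missing land-cover classes: {missing}")
        for k, v in self.landcover.items():
            if v.size != n:
                raise StructureError(f"land-cover '{k}' has length {v.size}, expected {n}")
            if np.any((v < -_FRACTION_TOL) | (v > 1 + _FRACTION_TOL)):
                bad = int(self.receptor_id[np.argmax((v < 0) | (v > 1))])
                raise ValidationError(f"land-cover fraction '{k}' outside [0,1] at receptor {bad}")
        total = sum(self.landcover[c] for c in LANDCOVER_CLASSES)
        off = np.abs(total - 1.0) > 1e-6
        if np.any(off):
            bad = int(self.receptor_id[np.argmax(off)])
            raise ValidationError(
                f"land-cover fractions sum to {total[np.argmax(off)]:.6f} (not 1) at receptor {bad}"
            )
        ny, nx = self.shape
        if ny * nx != n:
            raise StructureError(f"grid is ragged: {n} receptors cannot tile {ny} x {nx} nodes")

    # -- conversion ---------------------------------------------------------

    def to_frame(self, population: "PopulationLayer | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "receptor_id": self.receptor_id,
                "x_km": self.x_km,
                "y_km": self.y_km,
                **{f"f_{c}": self.landcover[c] for c in LANDCOVER_CLASSES},
            }
        )
        if population is not None:
            df["population"] = population.population
            df["y0_mortality"] = population.y0
        return df


@dataclass
class DeltaFields:
    """Per-pollutant dispersion deltas at full afforestation.

    ``dC`` holds concentration-reduction magnitudes (ug/m3 for PM2.5, ppb for
    ozone); ``ddep`` holds dry-deposition increments in tonnes/yr per
    receptor.  All values are nonnegative and zero at constrained receptors.
    """

    dC: dict[str, np.ndarray]  # keys: "pm25", "o3"
    ddep: dict[str, np.ndarray]  # keys: "nox", "pm25"

    def __post_init__(self) -> None:
        self.dC = {k: np.asarray(v, dtype=float) for k, v in self.dC.items()}
        self.ddep = {k: np.asarray(v, dtype=float) for k, v in self.ddep.items()}
        for group in (self.dC, self.ddep):
            for k, v in group.items():
                if np.any(v < 0):
                    raise ValidationError(f"negative delta value in '{k}'")

    def n_receptors(self) -> int:
        return next(iter(self.dC.values())).size


@dataclass
class PopulationLayer:
    """Exposed population and baseline all-cause mortality incidence."""

    population: np.ndarray  # persons per receptor
    y0: np.ndarray  # events / person / yr

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.y0 = np.asarray(self.y0, dtype=float)
        if np.any(self.population < 0):
            raise ValidationError("negative population")
        if np.any((self.y0 < 0) | (self.y0 > 1)):
            raise ValidationError("baseline incidence outside [0, 1]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_constraint_mask(grid: ReceptorGrid) -> np.ndarray:
    """Availability mask: True where ``developed + water < 0.5`` (strict).

    Receptors at exactly 50% developed-plus-water are treated as constrained
    (the conservative reading of the availability rule).  The mask depends on
    the developed and water fractions only and is stored on the grid.
    """
    mask = (grid.landcover["developed"] + grid.landcover["water"]) < 0.5
    grid.unconstrained = mask
    return mask


def delta_consistency_check(fields: DeltaFields, grid: ReceptorGrid) -> list[int]:
    """Report receptor ids with nonzero deltas on constrained cells.

    An empty report means the delta fields respect the availability mask:
    afforestation cannot change concentrations or deposition where no land
    can be converted.
    """
    constrained = ~grid.unconstrained
    leaky = np.zeros(grid.n_receptors, dtype=bool)
    for group in (fields.dC, fields.ddep):
        for v in group.values():
            leaky |= constrained & (v > 0)
    return [int(r) for r in grid.receptor_id[leaky]]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_landscape(
    grid_path, fields_path
) -> tuple[ReceptorGrid, DeltaFields, PopulationLayer]:
    """Read the receptor-grid and delta-field tables.

    Both files are UTF-8 CSV with a header row and one row per receptor,
    joined on ``receptor_id``.  Rows are canonicalized to (y, x) order, so
    the result is independent of on-disk row permutation.
    """
    gdf = pd.read_csv(grid_path)
    _require_columns(gdf, GRID_COLUMNS, grid_path)
    fdf = pd.read_csv(fields_path)
    _require_columns(fdf, FIELD_COLUMNS, fields_path)
    if len(gdf) != len(fdf):
        raise StructureError(
            f"grid table has {len(gdf)} rows but fields table has {len(fdf)}"
        )
    merged = gdf.merge(fdf, on="receptor_id", how="inner", validate="one_to_one")
    if len(merged) != len(gdf):
        raise StructureError("receptor_id sets of grid and fields tables differ")
    merged = merged.sort_values(["y_km", "x_km"], kind="mergesort").reset_index(drop=True)

    xs = np.unique(merged["x_km"].to_numpy())
    spacing = float(np.min(np.diff(xs))) if xs.size > 1 else 1.0

    grid = ReceptorGrid(
        receptor_id=merged["receptor_id"].to_numpy(),
        x_km=merged["x_km"].to_numpy(),
        y_km=merged["y_km"].to_numpy(),
        spacing_km=spacing,
        landcover={c: merged[f"f_{c}"].to_numpy() for c in LANDCOVER_CLASSES},
    )
    fields = DeltaFields(
        dC={"pm25": merged["dC_pm25"].to_numpy(), "o3": merged["dC_o3"].to_numpy()},
        ddep={"nox": merged["ddep_nox_t"].to_numpy(), "pm25": merged["ddep_pm25_t"].to_numpy()},
    )
    pop = PopulationLayer(
        population=merged["population"].to_numpy(), y0=merged["y0_mortality"].to_numpy()
    )
    return grid, fields, pop


def write_landscape(
    grid: ReceptorGrid,
    fields: DeltaFields,
    pop: PopulationLayer,
    grid_path,
    fields_path,
) -> None:
    """Write the two CSV tables consumed by :func:`read_landscape`."""
    grid.to_frame(pop).to_csv(grid_path, index=False)
    pd.DataFrame(
        {
            "receptor_id": grid.receptor_id,
            "dC_pm25": fields.dC["pm25"],
            "dC_o3": fields.dC["o3"],
            "ddep_nox_t": fields.ddep["nox"],
            "ddep_pm25_t": fields.ddep["pm25"],
        }
    ).to_csv(fields_path, index=False)


def grid_to_geojson(grid: ReceptorGrid, properties: dict[str, np.ndarray] | None = None) -> dict:
    """Export receptors as a GeoJSON FeatureCollection of points (planar km).

    Extra per-receptor arrays can be attached as feature properties for map
    rendering (e.g. population, plant year, availability).
    """
    properties = properties or {}
    feats = []
    for k in range(grid.n_receptors):
        props = {
            "receptor_id": int(grid.receptor_id[k]),
            "unconstrained": bool(grid.unconstrained[k]),
        }
        for name, arr in properties.items():
            v = arr[k]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                props[name] = None
            else:
                props[name] = v.item() if hasattr(v, "item") else v
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(grid.x_km[k]), float(grid.y_km[k])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}
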