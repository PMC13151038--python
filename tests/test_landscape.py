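import numpy as np
import pandas as pd
import pytest

from tesland import fixtures as fx
from tesland.errors import SchemaError, StructureError, ValidationError
from tesland.landscape import (
    ReceptorGrid,
    compute_constraint_mask,
    delta_consistency_check,
    grid_to_geojson,
    read_landscape,
    write_landscape,
)


def _bundle_paths(tmp_path, nx=3, ny=3, seed=0):
    spec = fx.FixtureSpec(nx=nx, ny=ny, seed=seed, urban_centers=1, horizon=5)
    return fx.generate_landscape(spec, tmp_path)


def test_round_trip_preserves_fields(tmp_path):
    """Write -> read preserves integers exactly and reals to 1e-12 relative."""
    paths = _bundle_paths(tmp_path / "a")
    grid, fields, pop = read_landscape(paths["grid"], paths["fields"])
    out = tmp_path / "b"
    out.mkdir()
    write_landscape(grid, fields, pop, out / "grid.csv", out / "fields.csv")
    grid2, fields2, pop2 = read_landscape(out / "grid.csv", out / "fields.csv")
    np.testing.assert_array_equal(grid.receptor_id, grid2.receptor_id)
    for c in grid.landcover:
        np.testing.assert_allclose(grid.landcover[c], grid2.landcover[c], rtol=1e-12)
    for p in fields.dC:
        np.testing.assert_allclose(fields.dC[p], fields2.dC[p], rtol=1e-12)
    for p in fields.ddep:
        np.testing.assert_allclose(fields.ddep[p], fields2.ddep[p], rtol=1e-12)
    np.testing.assert_array_equal(pop.population, pop2.population)


def test_three_by_three_fixture_reads_nine_receptors(tmp_path):
    paths = _bundle_paths(tmp_path)
    grid, fields, pop = read_landscape(paths["grid"], paths["fields"])
    assert grid.n_receptors == 9
    assert grid.shape == (3, 3)
    assert fields.n_receptors() == 9
    assert pop.population.size == 9


def test_default_grid_is_41_by_41_spanning_100_km(tmp_path):
    """The canonical receptor layout: 1681 nodes at 2.5 km over 100 x 100 km."""
    paths = fx.generate_landscape(fx.FixtureSpec(seed=0, horizon=5), tmp_path)
    grid, _, _ = read_landscape(paths["grid"], paths["fields"])
    assert grid.n_receptors == 1681
    assert grid.shape == (41, 41)
    assert grid.spacing_km == 2.5
    assert grid.x_km.max() - grid.x_km.min() == pytest.approx(100.0)
    assert grid.area_ha == pytest.approx(625.0)


def test_missing_column_raises_schema_error(tmp_path):
    paths = _bundle_paths(tmp_path)
    df = pd.read_csv(paths["grid"]).drop(columns=["population"])
    df.to_csv(paths["grid"], index=False)
    with pytest.raises(SchemaError, match="population"):
        read_landscape(paths["grid"], paths["fields"])


def test_bad_fraction_sum_names_offending_receptor(tmp_path):
    paths = _bundle_paths(tmp_path)
    df = pd.read_csv(paths["grid"])
    df.loc[df["receptor_id"] == 5, "f_forest"] += 0.2
    df.to_csv(paths["grid"], index=False)
    with pytest.raises(ValidationError, match="receptor 5"):
        read_landscape(paths["grid"], paths["fields"])


def test_ragged_grid_raises_structure_error(tmp_path):
    paths = _bundle_paths(tmp_path)
    for key in ("grid", "fields"):
        df = pd.read_csv(paths[key])
        df[df["receptor_id"] != 5].to_csv(paths[key], index=False)
    with pytest.raises(StructureError):
        read_landscape(paths["grid"], paths["fields"])


@pytest.mark.parametrize(
    "developed,water,expected_unconstrained",
    [
        (0.60, 0.00, False),  # majority developed: unavailable
        (0.20, 0.10, True),  # far below the threshold
        (0.30, 0.20, False),  # exactly 50%: strict inequality, unavailable
    ],
)
def test_availability_rule(developed, water, expected_unconstrained):
    rem = 1.0 - developed - water
    grid = ReceptorGrid(
        receptor_id=[0, 1],
        x_km=[0.0, 2.5],
        y_km=[0.0, 0.0],
        spacing_km=2.5,
        landcover={
            "developed": [developed, 0.0],
            "water": [water, 0.0],
            "forest": [rem / 2, 0.5],
            "agri_grass": [rem / 2, 0.5],
            "barren": [0.0, 0.0],
        },
    )
    mask = compute_constraint_mask(grid)
    assert bool(mask[0]) is expected_unconstrained
    # idempotent and a pure function of developed + water
    np.testing.assert_array_equal(mask, compute_constraint_mask(grid))


def test_unconstrained_count_invariant_under_row_permutation(tmp_path, rng):
    paths = _bundle_paths(tmp_path, nx=5, ny=5, seed=2)
    grid, _, _ = read_landscape(paths["grid"], paths["fields"])
    for key in ("grid", "fields"):
        df = pd.read_csv(paths[key])
        df.sample(frac=1.0, random_state=4).to_csv(paths[key], index=False)
    grid2, _, _ = read_landscape(paths["grid"], paths["fields"])
    assert int(grid.unconstrained.sum()) == int(grid2.unconstrained.sum())
    np.testing.assert_array_equal(grid.receptor_id, grid2.receptor_id)


def test_delta_consistency_report(tmp_path):
    paths = _bundle_paths(tmp_path, nx=5, ny=5, seed=2)
    grid, fields, _ = read_landscape(paths["grid"], paths["fields"])
    assert delta_consistency_check(fields, grid) == []
    constrained = np.where(~grid.unconstrained)[0]
    assert constrained.size > 0
    fields.dC["pm25"][constrained[0]] = 0.4  # inject one leak
    report = delta_consistency_check(fields, grid)
    assert report == [int(grid.receptor_id[constrained[0]])]


def test_geojson_export_has_one_feature_per_receptor(tmp_path):
    paths = _bundle_paths(tmp_path)
    grid, _, pop = read_landscape(paths["grid"], paths["fields"])
    geo = grid_to_geojson(grid, {"population": pop.population})
    assert geo["type"] == "FeatureCollection"
    assert len(geo["features"]) == grid.n_receptors
    assert all("population" in f["properties"] for f in geo["features"])
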