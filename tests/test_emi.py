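import numpy as np
import pandas as pd
import pytest

from soilplant.emi import (classify_eca_zones, interpolate_to_grid, ratio_map,
                           shift_correct, temperature_correct,
                           temperature_factor)
from soilplant.grids import DEFAULT_NODATA, GeoGrid, GridSpec, SurveyPointCloud


def _emi_cloud(x, y, eca=10.0, temp=25.0):
    n = len(x)
    df = pd.DataFrame({"x": x, "y": y, "timestamp": np.arange(n, dtype=float),
                       "eca_05": np.full(n, eca), "eca_10": np.full(n, eca),
                       "eca_18": np.full(n, eca),
                       "soil_temp": np.full(n, temp)})
    return SurveyPointCloud(df, "emi")


def test_temperature_factor_reference_points():
    assert temperature_factor(0.0) == pytest.approx(1.8504, abs=1e-12)
    assert temperature_factor(25.0) == pytest.approx(1.0, rel=1e-3)
    # high-precision evaluation of the exponential model at 25 degC
    assert temperature_factor(25.0) == pytest.approx(0.9994368562, abs=1e-9)
    assert temperature_factor(1000.0) == pytest.approx(0.4470, abs=1e-6)


def test_temperature_factor_strictly_decreasing():
    t = np.linspace(0, 50, 501)
    f = temperature_factor(t)
    assert (np.diff(f) < 0).all()


def test_temperature_correction_at_reference_is_nearly_identity():
    cloud = _emi_cloud(np.arange(5.0), np.zeros(5), eca=10.0, temp=25.0)
    out = temperature_correct(cloud)
    assert np.allclose(out.data["eca_10"], 10.0, rtol=1e-3)
    cold = temperature_correct(_emi_cloud(np.arange(5.0), np.zeros(5),
                                          eca=10.0, temp=0.0))
    assert np.allclose(cold.data["eca_10"], 18.504)


def test_temperature_requires_finite():
    with pytest.raises(ValueError):
        temperature_factor(np.nan)


def test_shift_straight_track_moves_exact_offset():
    cloud = _emi_cloud(np.arange(10.0), np.zeros(10))
    out = shift_correct(cloud, offset_m=4.5)
    assert np.allclose(out.data["x"], cloud.data["x"] + 4.5)
    assert np.allclose(out.data["y"], 0.0)
    back = shift_correct(cloud, offset_m=-4.5)
    assert np.allclose(back.data["x"], cloud.data["x"] - 4.5)


def test_shift_zero_offset_is_identity():
    cloud = _emi_cloud(np.arange(5.0), np.arange(5.0))
    out = shift_correct(cloud, offset_m=0.0)
    assert np.array_equal(out.data[["x", "y"]], cloud.data[["x", "y"]])


def test_shift_is_isometric_per_point_on_turning_track():
    """Every point moves exactly |offset| even through a right-angle turn,
    and interior headings match a finite-difference oracle."""
    x = np.r_[np.arange(10.0), np.full(9, 9.0)]
    y = np.r_[np.zeros(10), np.arange(1.0, 10.0)]
    cloud = _emi_cloud(x, y)
    out = shift_correct(cloud, offset_m=4.5)
    moved = np.hypot(out.data["x"] - x, out.data["y"] - y)
    assert np.allclose(moved, 4.5)
    # brute-force centered-difference oracle for interior points
    for i in range(1, len(x) - 1):
        hx, hy = x[i + 1] - x[i - 1], y[i + 1] - y[i - 1]
        nrm = np.hypot(hx, hy)
        assert out.data["x"][i] == pytest.approx(x[i] + 4.5 * hx / nrm)
        assert out.data["y"][i] == pytest.approx(y[i] + 4.5 * hy / nrm)


def test_shift_single_point_warns_and_keeps(caplog):
    cloud = _emi_cloud([1.0], [2.0])
    with caplog.at_level("WARNING", logger="soilplant"):
        out = shift_correct(cloud, offset_m=4.5)
    assert out.data["x"].iloc[0] == 1.0


def _grid(n=20, cell=1.0):
    return GridSpec(cell, (0.0, 0.0), n, n)


def test_idw_constant_cloud_gives_constant_surface():
    rng = np.random.default_rng(0)
    x, y = rng.uniform(0, 20, (2, 30))
    surf = interpolate_to_grid(_emi_cloud(x, y, eca=7.5), _grid(),
                               search_radius_m=50.0)
    vals = surf.values[surf.values != DEFAULT_NODATA]
    assert np.allclose(vals, 7.5)


def test_idw_two_point_symmetry():
    df = pd.DataFrame({"x": [0.0, 1.0], "y": [0.5, 0.5],
                       "timestamp": [0.0, 1.0],
                       "eca_05": [2.0, 4.0], "eca_10": [2.0, 4.0],
                       "eca_18": [2.0, 4.0], "soil_temp": [25.0, 25.0]})
    df = pd.concat([df, df.iloc[[0]].assign(x=0.5, y=10.0)],
                   ignore_index=True)  # third point far away
    cloud = SurveyPointCloud(df, "emi")
    grid = GridSpec(1.0, (0.0, 0.0), 1, 1)  # center at (0.5, 0.5)
    surf = interpolate_to_grid(cloud, grid, power=2.0, search_radius_m=2.0)
    assert surf.values[0, 0] == pytest.approx(3.0)


def test_idw_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    x, y = rng.uniform(0, 20, (2, 50))
    vals = rng.uniform(5, 50, 50)
    df = pd.DataFrame({"x": x, "y": y, "timestamp": np.arange(50.0),
                       "eca_05": vals, "eca_10": vals, "eca_18": vals,
                       "soil_temp": 25.0})
    cloud = SurveyPointCloud(df, "emi")
    grid = _grid(20)
    surf = interpolate_to_grid(cloud, grid, power=2.0, search_radius_m=8.0)
    xs, ys = grid.cell_centers()
    for j in range(20):
        for i in range(20):
            d = np.hypot(x - xs[i], y - ys[j])
            near = d <= 8.0
            if not near.any():
                expect = DEFAULT_NODATA
            else:
                w = 1.0 / d[near] ** 2
                expect = np.sum(w * vals[near]) / np.sum(w)
            assert surf.values[j, i] == pytest.approx(expect, abs=1e-10)


def test_idw_bounded_by_data_range():
    rng = np.random.default_rng(2)
    x, y = rng.uniform(0, 20, (2, 40))
    vals = rng.uniform(10, 20, 40)
    df = pd.DataFrame({"x": x, "y": y, "timestamp": np.arange(40.0),
                       "eca_05": vals, "eca_10": vals, "eca_18": vals,
                       "soil_temp": 25.0})
    surf = interpolate_to_grid(SurveyPointCloud(df, "emi"), _grid(),
                               search_radius_m=30.0)
    ok = surf.values != DEFAULT_NODATA
    assert surf.values[ok].min() >= 10.0 - 1e-9
    assert surf.values[ok].max() <= 20.0 + 1e-9


def test_ratio_map_identities():
    rng = np.random.default_rng(3)
    a = GeoGrid(rng.uniform(10, 30, (8, 8)), 2.0, (0, 0))
    b = GeoGrid(a.values / 1.2, 2.0, (0, 0))
    assert np.allclose(ratio_map(a, a).values, 1.0)
    assert np.allclose(ratio_map(a, b).values, 1.2)
    prod = ratio_map(a, b).values * ratio_map(b, a).values
    assert np.allclose(prod, 1.0)


def test_ratio_map_zero_and_nodata_cells():
    a = GeoGrid(np.full((4, 4), 10.0), 2.0, (0, 0))
    bv = np.full((4, 4), 5.0)
    bv[1, 1] = 0.0
    bv[2, 2] = DEFAULT_NODATA
    b = GeoGrid(bv, 2.0, (0, 0))
    out = ratio_map(a, b)
    assert out.values[1, 1] == DEFAULT_NODATA
    assert out.values[2, 2] == DEFAULT_NODATA
    assert out.values[0, 0] == 2.0


def test_ratio_map_grid_mismatch_rejected():
    a = GeoGrid(np.ones((4, 4)), 2.0, (0, 0))
    b = GeoGrid(np.ones((4, 4)), 2.0, (1, 0))
    with pytest.raises(ValueError):
        ratio_map(a, b)


def test_zone_median_split():
    vals = np.arange(1.0, 101.0).reshape(10, 10)
    zones = classify_eca_zones(GeoGrid(vals, 2.0, (0, 0)))
    assert (zones.values == 1).sum() == 50
    assert (zones.values == 0).sum() == 50
    with pytest.raises(ValueError):
        classify_eca_zones(GeoGrid(np.ones((5, 5)), 2.0, (0, 0)))


def test_zone_bimodal_recovery():
    """A strongly bimodal surface is split along its generating modes."""
    rng = np.random.default_rng(5)
    lowhigh = np.zeros((20, 20))
    lowhigh[:, 10:] = 1.0
    vals = np.where(lowhigh == 1, rng.normal(40, 1, (20, 20)),
                    rng.normal(10, 1, (20, 20)))
    zones = classify_eca_zones(GeoGrid(vals, 2.0, (0, 0)))
    agree = (zones.values == lowhigh).mean()
    assert agree >= 0.9
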