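import numpy as np
import pandas as pd
import pytest

from soilplant.grids import DEFAULT_NODATA, GeoGrid, GridSpec, SurveyPointCloud
from soilplant.spatial import (assign_sections, block_average, blocks_to_table,
                               corrected_correlation, covariability_report,
                               morans_i, sturges_classes, zone_summary)
from soilplant.synth import make_correlated_fields


def _coords(n):
    xs = np.arange(n) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    return np.column_stack([gx.ravel(), gy.ravel()])


# -- block averaging ---------------------------------------------------------

def test_block_average_constant_grid():
    g = GeoGrid(np.full((40, 40), 3.0), 1.0, (0, 0))
    out = block_average(g, GridSpec(20.0, (0.0, 0.0), 2, 2))
    assert np.allclose(out.values, 3.0)


def test_block_average_points():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 1.5, 2.0],
                       "timestamp": [0.0, 1.0, 2.0], "value": [2.0, 4.0, 6.0]})
    cloud = SurveyPointCloud(df, "value")
    out = block_average(cloud, GridSpec(20.0, (0.0, 0.0), 1, 1))
    assert out.values[0, 0] == pytest.approx(4.0)


def test_block_average_matches_brute_force():
    rng = np.random.default_rng(0)
    x, y = rng.uniform(0, 60, (2, 200))
    v = rng.normal(size=200)
    df = pd.DataFrame({"x": x, "y": y, "timestamp": np.arange(200.0),
                       "value": v})
    grid = GridSpec(20.0, (0.0, 0.0), 3, 3)
    out = block_average(SurveyPointCloud(df, "value"), grid)
    for j in range(3):
        for i in range(3):
            sel = (x >= i * 20) & (x < (i + 1) * 20) & \
                  (y >= j * 20) & (y < (j + 1) * 20)
            expect = v[sel].mean() if sel.any() else DEFAULT_NODATA
            assert out.values[j, i] == pytest.approx(expect)


def test_block_average_empty_blocks_nodata():
    g = GeoGrid(np.full((10, 10), DEFAULT_NODATA), 1.0, (0, 0))
    g.values[0, 0] = 5.0
    out = block_average(g, GridSpec(5.0, (0.0, 0.0), 2, 2))
    assert out.values[0, 0] == 5.0
    assert out.values[1, 1] == DEFAULT_NODATA


# -- Sturges -----------------------------------------------------------------

@pytest.mark.parametrize("n,k", [(1024, 11), (2, 2), (100, 8), (400, 10)])
def test_sturges_values(n, k):
    assert sturges_classes(n) == k


def test_sturges_rejects_small_n():
    with pytest.raises(ValueError):
        sturges_classes(1)


# -- Moran's I ---------------------------------------------------------------

def test_morans_i_checkerboard_rook():
    vals = np.indices((4, 4)).sum(axis=0) % 2
    assert morans_i(vals, _coords(4), "rook") == pytest.approx(-1.0)


def test_morans_i_matches_brute_force_double_sum():
    rng = np.random.default_rng(1)
    coords = _coords(6)
    n = 36
    for _ in range(10):
        x = rng.normal(size=n)
        got = morans_i(x, coords, "rook")
        d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                     coords[:, None, 1] - coords[None, :, 1])
        w = ((d > 0) & (d <= 1.0 + 1e-9)).astype(float)
        z = x - x.mean()
        expect = n / w.sum() * (z @ w @ z) / (z @ z)
        assert got == pytest.approx(expect, abs=1e-12)


def test_morans_i_permutation_null_expectation():
    rng = np.random.default_rng(2)
    coords = _coords(6)
    x = rng.normal(size=36)
    vals = [morans_i(rng.permutation(x), coords, "rook")
            for _ in range(2000)]
    assert np.mean(vals) == pytest.approx(-1 / 35, abs=0.01)


def test_morans_i_constant_rejected():
    with pytest.raises(ValueError):
        morans_i(np.ones(16), _coords(4))


# -- corrected correlation ----------------------------------------------------

def test_identical_variables_give_r_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=100)
    res = corrected_correlation(x, x, _coords(10))
    assert res.r == pytest.approx(1.0)
    assert res.p_corrected < 0.001
    assert res.stars == "***"


def test_effective_n_near_n_for_white_noise():
    mh = []
    for s in range(100):
        gx, gy = make_correlated_fields(20, 1e-12, 0.0, seed=s)
        res = corrected_correlation(gx.values.ravel(), gy.values.ravel(),
                                    _coords(20) * 20.0)
        mh.append(res.m_hat)
    assert np.mean(mh) == pytest.approx(400, rel=0.10)


def test_effective_n_shrinks_under_autocorrelation():
    gx, gy = make_correlated_fields(20, 100.0, 0.0, seed=1)
    res = corrected_correlation(gx.values.ravel(), gy.values.ravel(),
                                _coords(20) * 20.0)
    assert 2 < res.m_hat < 400
    assert res.k_classes == sturges_classes(400)


def test_corrected_p_weaker_than_naive_under_autocorrelation():
    for s in range(5):
        gx, gy = make_correlated_fields(20, 100.0, 0.4, seed=s)
        res = corrected_correlation(gx.values.ravel(), gy.values.ravel(),
                                    _coords(20) * 20.0)
        if res.m_hat < res.n and res.r != 0:
            assert res.p_corrected >= res.p_naive


def test_r_invariant_to_affine_rescaling():
    rng = np.random.default_rng(4)
    x = rng.normal(size=100)
    y = rng.normal(size=100)
    coords = _coords(10)
    r0 = corrected_correlation(x, y, coords).r
    r1 = corrected_correlation(3.0 * x - 7.0, 0.5 * y + 2.0, coords).r
    assert r1 == pytest.approx(r0, abs=1e-12)


def test_coincident_points_rejected():
    x = np.random.default_rng(0).normal(size=12)
    coords = np.zeros((12, 2))
    with pytest.raises(ValueError):
        corrected_correlation(x, x + 1e-9, coords)


# -- tables, sections, reports ------------------------------------------------

def _block_table(seed=0, rho=0.5, range_m=1e-12):
    gx, gy = make_correlated_fields(12, range_m, rho, seed=seed)
    return blocks_to_table({"a": gx, "b": gy})


def test_blocks_to_table_alignment_and_nan():
    g1 = GeoGrid(np.arange(4.0).reshape(2, 2), 20.0, (0, 0))
    vals = np.arange(4.0).reshape(2, 2)
    vals[0, 0] = DEFAULT_NODATA
    g2 = GeoGrid(vals, 20.0, (0, 0))
    t = blocks_to_table({"p": g1, "q": g2})
    assert len(t) == 4
    assert np.isnan(t["q"].iloc[0])
    assert t["p"].iloc[0] == 0.0


def test_assign_sections_equal_thirds():
    t = pd.DataFrame({"x": [5.0, 45.0, 95.0], "y": [0.0] * 3})
    out = assign_sections(t, extent=(0.0, 100.0))
    assert list(out["section"]) == ["west", "center", "east"]


def test_zone_summary_reproduces_planted_means():
    t = pd.DataFrame({
        "section": ["west"] * 4,
        "eca_zone": [1.0, 1.0, 0.0, 0.0],
        "abundance": [10.0, 10.0, 50.0, 50.0],
    })
    out = zone_summary(t, ["abundance"])
    high = out[(out.zone == 1.0)]["mean"].iloc[0]
    low = out[(out.zone == 0.0)]["mean"].iloc[0]
    assert high == 10.0 and low == 50.0
    assert out["n_blocks"].sum() == 4


def test_covariability_report_self_pair():
    t = _block_table()
    t["section"] = "all"
    rep = covariability_report(t, [("a", "a")])
    assert rep["r"].iloc[0] == pytest.approx(1.0)
    assert rep["significance"].iloc[0] == "***"


def test_covariability_report_skips_small_strata(caplog):
    t = _block_table().head(5)
    t["section"] = "tiny"
    with caplog.at_level("WARNING", logger="soilplant"):
        rep = covariability_report(t, [("a", "b")])
    assert rep.empty


def test_null_fields_mostly_nonsignificant():
    """Independent autocorrelated fields rarely reach significance under
    the corrected test."""
    ns = 0
    trials = 60
    for s in range(trials):
        gx, gy = make_correlated_fields(12, 60.0, 0.0, seed=s)
        t = blocks_to_table({"a": gx, "b": gy})
        rep = covariability_report(t, [("a", "b")], section_col=None)
        ns += rep["significance"].iloc[0] == "(-)"
    assert ns / trials >= 0.85
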