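"""Temperature fields: sampling, downscaling, and field comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermobias import (
    ScenarioTable,
    TemperatureField,
    compare_fields,
    downscale_bilinear,
    sample_temperature,
)
from thermobias.climate import sample_temperatures


def make_field(values, lon=None, lat=None, **kw):
    values = np.asarray(values, dtype=float)
    lon = np.arange(values.shape[1], dtype=float) if lon is None else lon
    lat = np.arange(values.shape[0], dtype=float) if lat is None else lat
    return TemperatureField(lon, lat, values, **kw)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sample_constant_ocean_field():
    fld = make_field(np.full((5, 5), 20.0))
    assert sample_temperature(fld, 2.2, 3.9) == 20.0


def test_sample_masked_cell_unique_neighbor():
    vals = np.full((3, 3), np.nan)
    vals[1, 2] = 18.0
    fld = make_field(vals)
    assert sample_temperature(fld, 1.0, 1.0, max_search_cells=1) == 18.0


def test_sample_beyond_search_radius_is_missing():
    vals = np.full((5, 5), np.nan)
    vals[4, 4] = 15.0
    fld = make_field(vals)
    assert np.isnan(sample_temperature(fld, 0.0, 0.0, max_search_cells=2))


def _bruteforce_nearest(fld, lon, lat, r):
    from thermobias.climate import _great_circle_km

    i = int(np.argmin(np.abs(fld.lat_axis - lat)))
    j = int(np.argmin(np.abs(fld.lon_axis - lon)))
    if np.isfinite(fld.values[i, j]):
        return fld.values[i, j]
    best = None
    for ii in range(max(i - r, 0), min(i + r + 1, fld.lat_axis.size)):
        for jj in range(max(j - r, 0), min(j + r + 1, fld.lon_axis.size)):
            if not np.isfinite(fld.values[ii, jj]):
                continue
            d = float(_great_circle_km(lon, lat, fld.lon_axis[jj], fld.lat_axis[ii]))
            key = (round(d, 9), abs(fld.lat_axis[ii] - lat), abs(fld.lon_axis[jj] - lon))
            if best is None or key < best[0]:
                best = (key, fld.values[ii, jj])
    return np.nan if best is None else best[1]


def test_sample_matches_bruteforce_scan():
    rng = np.random.default_rng(3)
    vals = rng.uniform(5, 30, (12, 15))
    vals[rng.random((12, 15)) < 0.5] = np.nan
    fld = make_field(vals, lon=np.linspace(-20, 8, 15), lat=np.linspace(20, 42, 12))
    lons = rng.uniform(-20, 8, 100)
    lats = rng.uniform(20, 42, 100)
    got = sample_temperatures(fld, lons, lats, max_search_cells=2)
    for k in range(100):
        expect = _bruteforce_nearest(fld, lons[k], lats[k], 2)
        assert (np.isnan(got[k]) and np.isnan(expect)) or got[k] == expect


def test_sampling_order_invariant():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 30, (8, 8))
    vals[rng.random((8, 8)) < 0.3] = np.nan
    fld = make_field(vals)
    lons, lats = rng.uniform(0, 7, 50), rng.uniform(0, 7, 50)
    a = sample_temperatures(fld, lons, lats)
    perm = rng.permutation(50)
    b = sample_temperatures(fld, lons[perm], lats[perm])
    np.testing.assert_array_equal(a[perm], b)


# ---------------------------------------------------------------------------
# downscaling
# ---------------------------------------------------------------------------

def test_downscale_constant_and_center_identity():
    fld = make_field(np.full((4, 4), 12.5))
    out = downscale_bilinear(fld, np.linspace(0, 3, 7), np.linspace(0, 3, 7))
    np.testing.assert_allclose(out.values, 12.5)

    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 30, (4, 4))
    fld = make_field(vals)
    out = downscale_bilinear(fld, fld.lon_axis, fld.lat_axis)
    np.testing.assert_allclose(out.values, vals)


def test_downscale_midpoint_is_corner_mean():
    vals = np.array([[1.0, 3.0], [5.0, 7.0]])
    fld = make_field(vals)
    out = downscale_bilinear(fld, np.array([0.5]), np.array([0.5]))
    assert out.values[0, 0] == pytest.approx((1 + 3 + 5 + 7) / 4)


def test_downscale_mask_renormalisation_and_bounds():
    vals = np.array([[1.0, 3.0], [np.nan, 7.0]])
    fld = make_field(vals)
    out = downscale_bilinear(fld, np.array([0.5]), np.array([0.5]))
    # Three unmasked corners with equal bilinear weight.
    assert out.values[0, 0] == pytest.approx((1 + 3 + 7) / 3)

    rng = np.random.default_rng(2)
    vals = rng.uniform(-2, 30, (6, 6))
    vals[rng.random((6, 6)) < 0.3] = np.nan
    fld = make_field(vals)
    out = downscale_bilinear(fld, np.linspace(0, 5, 21), np.linspace(0, 5, 21))
    finite = out.values[np.isfinite(out.values)]
    assert finite.min() >= np.nanmin(vals) - 1e-12
    assert finite.max() <= np.nanmax(vals) + 1e-12


def test_downscale_outside_bbox_raises():
    fld = make_field(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        downscale_bilinear(fld, np.array([-1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# field comparison
# ---------------------------------------------------------------------------

def test_compare_identical_fields():
    rng = np.random.default_rng(4)
    vals = rng.uniform(0, 30, (6, 6))
    vals[0, 0] = np.nan
    a = make_field(vals)
    rho, rmse, diff = compare_fields(a, a)
    assert rho == 1.0 and rmse == 0.0
    assert np.isnan(diff[0, 0])


def test_compare_offset_fields():
    rng = np.random.default_rng(6)
    vals = rng.uniform(0, 30, (5, 5))
    a = make_field(vals)
    b = make_field(vals + 2.0)
    rho, rmse, _ = compare_fields(b, a)
    assert rho == 1.0
    assert rmse == pytest.approx(2.0)


def test_compare_matches_independent_statistics():
    rng = np.random.default_rng(7)
    va = rng.uniform(0, 30, (5, 10))
    vb = rng.uniform(0, 30, (5, 10))
    a, b = make_field(va), make_field(vb)
    rho, rmse, diff = compare_fields(a, b)
    # Oracle: rank-transform + Pearson formula, plain RMS.
    ra = np.argsort(np.argsort(va.ravel()))
    rb = np.argsort(np.argsort(vb.ravel()))
    rho_expect = np.corrcoef(ra, rb)[0, 1]
    assert rho == pytest.approx(rho_expect, abs=1e-10)
    assert rmse == pytest.approx(np.sqrt(np.mean((va - vb) ** 2)), abs=1e-10)
    np.testing.assert_allclose(diff, va - vb)


def test_compare_mean_centered_variant():
    rng = np.random.default_rng(8)
    vals = rng.uniform(0, 30, (4, 4))
    a, b = make_field(vals), make_field(vals + 2.0)
    _, rmse, _ = compare_fields(b, a, mean_centered_rmse=True)
    assert rmse == pytest.approx(0.0, abs=1e-12)


def test_compare_too_few_cells_raises():
    vals = np.full((3, 3), np.nan)
    vals[0, :2] = 1.0
    a = make_field(vals)
    with pytest.raises(ValueError, match="fewer than 3"):
        compare_fields(a, a)


def test_compare_requires_identical_axes():
    a = make_field(np.zeros((3, 3)))
    b = make_field(np.zeros((3, 3)), lon=np.array([0.0, 1.0, 2.5]))
    with pytest.raises(ValueError):
        compare_fields(a, b)


# ---------------------------------------------------------------------------
# field I/O and plausibility
# ---------------------------------------------------------------------------

def test_field_roundtrip_netcdf_and_csv(tmp_path):
    rng = np.random.default_rng(9)
    vals = rng.uniform(0, 30, (4, 6))
    vals[1, 1] = np.nan
    fld = make_field(vals, geography_tag="185Ma", scenario_tag="main")
    fld.to_netcdf(tmp_path / "f.nc")
    back = TemperatureField.from_netcdf(tmp_path / "f.nc")
    np.testing.assert_allclose(back.values, vals)
    assert back.geography_tag == "185Ma"

    fld.to_csv(tmp_path / "f.csv")
    back2 = TemperatureField.from_csv(tmp_path / "f.csv")
    np.testing.assert_allclose(back2.values, vals)


def test_field_plausibility_window():
    with pytest.raises(ValueError, match="plausibility"):
        make_field(np.full((3, 3), 80.0))


# ---------------------------------------------------------------------------
# scenario table
# ---------------------------------------------------------------------------

def test_scenario_defaults_and_yaml_roundtrip(tmp_path):
    tab = ScenarioTable()
    assert tab.main("Exaratum") == 1000 and tab.secondary("Exaratum") == 1500
    assert tab.main("Spinatum") == 400 and tab.secondary("Spinatum") == 300
    assert tab.main("Falciferum") == 750 and tab.secondary("Falciferum") == 1000
    assert tab.main("Tenuicostatum") == tab.secondary("Tenuicostatum") == 500
    assert tab.main("Bifrons") == tab.secondary("Bifrons") == 750
    assert tab.main("Margaritatus") == 400

    tab.to_yaml(tmp_path / "s.yaml")
    back = ScenarioTable.from_yaml(tmp_path / "s.yaml")
    assert back.scenarios == tab.scenarios
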