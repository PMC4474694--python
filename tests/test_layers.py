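import datetime as dt

import numpy as np
import pytest

from seaniche import (EnvStack, GridSpec, correlation_screen, distance_to_shore,
                      interpolate_depth, seasonal_sst_stats, slope_from_depth)
from seaniche.occurrences import season_of_date

from conftest import make_raster


# ---------------------------------------------------------------------------
# depth interpolation


@pytest.mark.parametrize("method", ["kriging", "idw"])
def test_constant_depth_field_recovered(method):
    grid = GridSpec(10, 10, 100.0, origin_y=1000.0)
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 1000, 20),
                           rng.uniform(0, 1000, 20),
                           np.full(20, 50.0)])
    r = interpolate_depth(pts, grid, method=method)
    np.testing.assert_allclose(r.valid_values(), 50.0)


def test_kriging_recovers_plane_within_one_percent():
    grid = GridSpec(20, 20, 100.0, origin_y=2000.0)
    xg, yg = grid.cell_centers()
    plane = 30.0 + 0.01 * xg + 0.005 * yg
    idx = np.r_[0:20:2, 19]  # dense regular sample covering the full extent
    sub = np.ix_(idx, idx)
    pts = np.column_stack([xg[sub].ravel(), yg[sub].ravel(),
                           plane[sub].ravel()])
    r = interpolate_depth(pts, grid, method="kriging")
    np.testing.assert_allclose(r.valid_values(), plane[grid.mask], rtol=0.01)


def test_interpolation_exact_at_sounding_cells():
    grid = GridSpec(12, 12, 100.0, origin_y=1200.0)
    xg, yg = grid.cell_centers()
    rng = np.random.default_rng(1)
    idx = rng.choice(144, 25, replace=False)
    depths = rng.uniform(5, 80, 25)
    pts = np.column_stack([xg.ravel()[idx], yg.ravel()[idx], depths])
    r = interpolate_depth(pts, grid, method="kriging")
    np.testing.assert_allclose(r.values.ravel()[idx], depths, atol=1e-6)


def test_corner_cluster_still_covers_all_marine_cells():
    grid = GridSpec(15, 15, 100.0, origin_y=1500.0)
    rng = np.random.default_rng(2)
    pts = np.column_stack([rng.uniform(0, 200, 12), rng.uniform(1300, 1500, 12),
                           rng.uniform(10, 30, 12)])
    r = interpolate_depth(pts, grid)
    assert np.isfinite(r.valid_values()).all()


def test_interpolation_input_contracts():
    grid = GridSpec(5, 5, 100.0, origin_y=500.0)
    with pytest.raises(ValueError, match="at least 3"):
        interpolate_depth([[10, 10, 5], [20, 20, 6]], grid)
    with pytest.raises(ValueError, match="collinear"):
        interpolate_depth([[0, 0, 5], [100, 100, 6], [200, 200, 7]], grid)
    with pytest.raises(ValueError, match="outside"):
        interpolate_depth([[9000, 9000, 5], [9100, 9000, 6], [9000, 9100, 7]],
                          grid)
    with pytest.raises(ValueError, match="non-negative"):
        interpolate_depth([[10, 10, -5], [20, 20, 6], [20, 10, 7]], grid)


# ---------------------------------------------------------------------------
# slope


def test_flat_depth_gives_zero_slope():
    r = make_raster(np.full((6, 6), 80.0))
    s = slope_from_depth(r)
    np.testing.assert_allclose(s.valid_values(), 0.0)


def test_rook_drop_of_3p67m_at_1km_is_0p21_degrees():
    # a drop of ~3.67 m in a 1000 m run is a slope of 0.21 degrees
    vals = np.full((3, 3), 10.0)
    vals[1, 2] = 10.0 + 3.665
    s = slope_from_depth(make_raster(vals, cell_size=1000.0))
    assert s.values[1, 1] == pytest.approx(0.21, abs=0.005)
    assert round(np.tan(np.radians(0.21)) * 1000.0) == 4


def test_diagonal_drop_uses_sqrt2_run():
    vals = np.full((3, 3), 10.0)
    vals[0, 0] = 20.0  # 10 m drop toward the diagonal neighbour
    s = slope_from_depth(make_raster(vals, cell_size=1000.0))
    expected = np.degrees(np.arctan(10.0 / (1000.0 * np.sqrt(2.0))))
    assert s.values[1, 1] == pytest.approx(expected, abs=1e-9)
    assert s.values[1, 1] != pytest.approx(
        np.degrees(np.arctan(10.0 / 1000.0)), abs=0.05)


def test_slope_matches_bruteforce_eight_neighbour_loop():
    rng = np.random.default_rng(4)
    vals = rng.uniform(0, 120, size=(12, 14))
    mask = rng.random((12, 14)) > 0.2
    r = make_raster(vals, cell_size=500.0, mask=mask)
    s = slope_from_depth(r)
    for i in range(12):
        for j in range(14):
            if not mask[i, j]:
                assert np.isnan(s.values[i, j])
                continue
            best = -np.inf
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < 12 and 0 <= jj < 14 and mask[ii, jj]):
                        continue
                    d = 500.0 * (np.sqrt(2) if di and dj else 1.0)
                    best = max(best, np.degrees(
                        np.arctan(abs(vals[ii, jj] - vals[i, j]) / d)))
            if best == -np.inf:
                assert not s.grid.mask[i, j]
            else:
                assert s.values[i, j] == pytest.approx(best, abs=1e-10)


# ---------------------------------------------------------------------------
# distance to shore


def test_distance_is_cell_size_next_to_land(open_sea_grid):
    d = distance_to_shore(open_sea_grid)
    np.testing.assert_allclose(d.values[:, 1], 1000.0)


def test_straight_coast_distance_is_exact_offsets(open_sea_grid):
    d = distance_to_shore(open_sea_grid)
    for col in range(1, 12):
        np.testing.assert_allclose(d.values[:, col], col * 1000.0)


def test_single_land_cell_gives_radially_symmetric_field():
    mask = np.ones((11, 11), dtype=bool)
    mask[5, 5] = False
    grid = GridSpec(11, 11, 100.0, origin_y=1100.0, mask=mask)
    d = distance_to_shore(grid)
    rows, cols = np.indices((11, 11))
    expected = 100.0 * np.hypot(rows - 5, cols - 5)
    np.testing.assert_allclose(d.values[mask], expected[mask])


def test_all_marine_mask_rejected():
    with pytest.raises(ValueError, match="shoreline"):
        distance_to_shore(GridSpec(6, 6, 100.0, origin_y=600.0))


# ---------------------------------------------------------------------------
# seasonal SST statistics


def test_two_value_series_mean_and_sample_sd():
    a = make_raster(np.full((4, 4), 12.0))
    b = make_raster(np.full((4, 4), 14.0))
    series = [(dt.date(2003, 11, 2), a), (dt.date(2004, 2, 9), b),
              (dt.date(2003, 5, 1), a), (dt.date(2003, 8, 1), b)]
    stats = seasonal_sst_stats(series)
    np.testing.assert_allclose(stats["warm"][0].valid_values(), 13.0)
    np.testing.assert_allclose(stats["warm"][1].valid_values(), np.sqrt(2.0))


def test_constant_series_has_zero_sd():
    a = make_raster(np.full((4, 4), 9.0))
    series = [(dt.date(2003, 1, 1), a), (dt.date(2003, 2, 1), a),
              (dt.date(2003, 6, 1), a), (dt.date(2003, 7, 1), a)]
    stats = seasonal_sst_stats(series)
    assert np.nanmax(stats["cold"][1].values) == 0.0


def test_season_assignment_of_march_and_april():
    assert season_of_date("2005-03-15") == "warm"
    assert season_of_date("2005-04-15") == "cold"


def test_single_date_season_rejected():
    a = make_raster(np.full((3, 3), 9.0))
    series = [(dt.date(2003, 1, 1), a), (dt.date(2003, 6, 1), a),
              (dt.date(2003, 7, 1), a)]
    with pytest.raises(ValueError, match="at least 2"):
        seasonal_sst_stats(series)


# ---------------------------------------------------------------------------
# correlation screen


def _stack_from_arrays(**named):
    return EnvStack([make_raster(v, name=k) for k, v in named.items()])


def test_correlation_with_duplicate_layer_is_one_and_flagged():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(10, 10))
    stack = _stack_from_arrays(a=x, b=x.copy())
    matrix, flagged = correlation_screen(stack)
    assert matrix.loc["a", "b"] == pytest.approx(1.0)
    assert len(flagged) == 1
    assert flagged[0][0] == "a" and flagged[0][1] == "b"
    assert flagged[0][2] == pytest.approx(1.0)


def test_r_069_pair_is_not_flagged_at_default_threshold():
    # a pair correlated at exactly 0.69 is retained, not flagged
    rng = np.random.default_rng(6)
    n = 400
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean() - x * (x @ (z - z.mean())) / (x @ x)
    z /= z.std()
    y = 0.69 * x + np.sqrt(1 - 0.69 ** 2) * z
    stack = _stack_from_arrays(depth=x.reshape(20, 20),
                               sst_cold=y.reshape(20, 20))
    matrix, flagged = correlation_screen(stack, threshold=0.7)
    assert matrix.loc["depth", "sst_cold"] == pytest.approx(0.69, abs=1e-9)
    assert flagged == []


def test_independent_noise_layers_have_small_correlation():
    rng = np.random.default_rng(7)
    stack = _stack_from_arrays(a=rng.normal(size=(100, 100)),
                               b=rng.normal(size=(100, 100)))
    matrix, flagged = correlation_screen(stack)
    assert abs(matrix.loc["a", "b"]) < 0.1
    assert flagged == []


def test_constant_layer_reports_nan_with_warning():
    rng = np.random.default_rng(8)
    stack = _stack_from_arrays(a=rng.normal(size=(6, 6)),
                               b=np.full((6, 6), 3.0))
    with pytest.warns(UserWarning, match="constant"):
        matrix, _ = correlation_screen(stack)
    assert np.isnan(matrix.loc["a", "b"])
    assert matrix.loc["b", "b"] == 1.0


def test_spearman_mode_matches_rank_pearson():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(15, 15))
    stack = _stack_from_arrays(a=x, b=np.exp(x))  # monotone transform
    matrix, _ = correlation_screen(stack, method="spearman")
    assert matrix.loc["a", "b"] == pytest.approx(1.0)
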