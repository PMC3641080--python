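"""Kernel UD estimation, volume contours, river clipping, centroids."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box
from shapely.ops import unary_union

import crocrange as cr
from crocrange.kud import (DensitySurface, KdeConfig, clip_to_river,
                           cumulative_kuds, estimate_kde, kud_centroid,
                           volume_contour)
from crocrange.raster import RiverMask, rasterize_river


def _brute_force_density(xy, surface, h):
    """Independent double-loop KDE oracle, normalised like the estimator."""
    xs, ys = surface.cell_centres()
    dens = np.zeros(surface.shape)
    for r, y in enumerate(ys):
        for c, x in enumerate(xs):
            for px, py in xy:
                dens[r, c] += np.exp(-((x - px) ** 2 + (y - py) ** 2)
                                     / (2 * h * h))
    return dens / dens.sum()


def test_kde_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 200, size=(20, 2))
    cfg = KdeConfig(h_m=100.0, grid_cell_m=50.0, extent_pad_m=400.0,
                    cutoff_sd=1e6)
    surface = estimate_kde(xy, cfg)
    assert surface.density.size <= 400
    oracle = _brute_force_density(xy, surface, 100.0)
    np.testing.assert_allclose(surface.density, oracle, rtol=1e-10)


def test_kernel_truncation_error_is_negligible():
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 500, size=(30, 2))
    cfg = KdeConfig(h_m=100.0, grid_cell_m=50.0, extent_pad_m=1500.0)
    full = estimate_kde(xy, KdeConfig(h_m=100.0, grid_cell_m=50.0,
                                      extent_pad_m=1500.0, cutoff_sd=1e6))
    trunc = estimate_kde(xy, cfg)
    assert np.abs(full.density - trunc.density).max() < 1e-12 * full.density.max()


def test_identical_fixes_peak_and_normalisation():
    xy = np.tile([[500.0, 500.0]], (5, 1))
    surface = estimate_kde(xy, KdeConfig(h_m=200.0, extent_pad_m=800.0))
    assert surface.density.sum() == pytest.approx(1.0, abs=1e-9)
    r, c = np.unravel_index(surface.density.argmax(), surface.shape)
    xs, ys = surface.cell_centres()
    assert abs(xs[c] - 500.0) <= 25.0 and abs(ys[r] - 500.0) <= 25.0


def test_duplicating_every_fix_leaves_surface_unchanged():
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 1000, size=(10, 2))
    cfg = KdeConfig(h_m=300.0)
    a = estimate_kde(xy, cfg)
    b = estimate_kde(np.vstack([xy, xy]), cfg)
    np.testing.assert_allclose(a.density, b.density, rtol=1e-12)


def test_too_few_fixes_refused():
    with pytest.raises(ValueError, match="at least 5"):
        estimate_kde(np.zeros((4, 2)), KdeConfig())


def test_uniform_surface_contour_cell_count():
    surface = DensitySurface(0, 0, 50.0, np.full((10, 10), 0.01))
    contour = volume_contour(surface, 0.50)
    assert contour.n_cells == 50
    assert contour.area_km2 == pytest.approx(50 * 2500 / 1e6)


@pytest.fixture(scope="module")
def gaussian_surface():
    rng = np.random.default_rng(7)
    xy = rng.normal(2000.0, 400.0, size=(40, 2))
    return estimate_kde(xy, KdeConfig(h_m=300.0))


def test_contour_mass_and_minimality(gaussian_surface):
    for level in (0.50, 0.95):
        contour = volume_contour(gaussian_surface, level)
        mass = gaussian_surface.density[contour.cells].sum()
        assert mass >= level - 1e-12
        lowest = gaussian_surface.density[contour.cells].min()
        assert mass - lowest < level


def test_contour_nesting(gaussian_surface):
    k50 = volume_contour(gaussian_surface, 0.50)
    k95 = volume_contour(gaussian_surface, 0.95)
    assert (k95.cells | k50.cells).sum() == k95.cells.sum()
    assert k50.n_cells < k95.n_cells


def test_clip_fully_inside_water_is_identity(gaussian_surface):
    k50 = volume_contour(gaussian_surface, 0.50)
    mask = RiverMask(gaussian_surface.origin_x, gaussian_surface.origin_y,
                     50.0, np.ones(gaussian_surface.shape, dtype=bool))
    clipped = clip_to_river(k50, mask)
    assert clipped.reduction_percent == 0.0
    assert clipped.area_km2 == k50.area_km2


def test_clip_arithmetic():
    cells = np.zeros((10, 10), dtype=bool)
    cells[:10, :10] = True                      # 100-cell contour
    contour = cr.VolumeContour(0.95, 0.0, 0.0, 50.0, cells)
    water = np.zeros((10, 10), dtype=bool)
    water[0, :10] = True                        # 10 water cells inside
    clipped = clip_to_river(contour, RiverMask(0.0, 0.0, 50.0, water))
    assert clipped.n_cells == 10
    assert clipped.reduction_percent == pytest.approx(90.0)
    assert clipped.area_km2 <= contour.area_km2


def test_clip_without_intersection_is_error(gaussian_surface):
    k50 = volume_contour(gaussian_surface, 0.50)
    far = RiverMask(1e6, 1e6, 50.0, np.ones((5, 5), dtype=bool))
    with pytest.raises(ValueError):
        clip_to_river(k50, far)


def test_centroid_of_symmetric_peak_on_straight_river():
    mask = rasterize_river(box(0, 0, 5000, 100), 50.0, bounds=(0, 0, 5000, 100))
    rng = np.random.default_rng(5)
    xy = np.column_stack([2500.0 + rng.normal(0, 300, 60),
                          np.full(60, 50.0)])
    surface = estimate_kde(xy, KdeConfig(h_m=300.0), align_to=mask)
    k50 = clip_to_river(volume_contour(surface, 0.50), mask)
    centroid = kud_centroid(k50, surface, mask)
    assert abs(centroid.x - 2500.0) <= 200.0
    assert mask.water[centroid.row, centroid.col]


def test_centroid_on_u_shaped_river_lands_on_water():
    arms = unary_union([box(0, 0, 200, 3000), box(1800, 0, 2000, 3000),
                        box(0, 0, 2000, 200)])
    mask = rasterize_river(arms, 50.0, bounds=(0, 0, 2000, 3000))
    xy = np.array([[100.0, 2800.0]] * 20 + [[1900.0, 2800.0]] * 20)
    xy = xy + np.random.default_rng(8).normal(0, 50, xy.shape)
    surface = estimate_kde(xy, KdeConfig(h_m=200.0), align_to=mask)
    k50 = clip_to_river(volume_contour(surface, 0.50), mask)
    centroid = kud_centroid(k50, surface, mask)
    # the unweighted planar mean falls between the arms, on land
    assert mask.water[centroid.row, centroid.col]


def test_smaller_bandwidth_shrinks_compact_cloud_area():
    rng = np.random.default_rng(9)
    xy = rng.normal(0.0, 100.0, size=(50, 2))     # spread << 750 m
    wide = estimate_kde(xy, KdeConfig(h_m=750.0))
    narrow = estimate_kde(xy, KdeConfig(h_m=200.0, extent_pad_m=3000.0))
    assert volume_contour(narrow, 0.95).area_km2 \
        <= volume_contour(wide, 0.95).area_km2


def _daily_track(x_per_day, y=150.0, start="2010-09-01"):
    rows = []
    for d, x in enumerate(x_per_day):
        for hour in (8, 18):
            rows.append({"timestamp": pd.Timestamp(start)
                         + pd.Timedelta(days=d, hours=hour),
                         "x_m": x, "y_m": y})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def long_straight_mask():
    return rasterize_river(box(0, 0, 200_000, 300), 50.0,
                           bounds=(0, 0, 200_000, 300))


def test_cumulative_areas_increase_under_drift(long_straight_mask):
    track = _daily_track(1000.0 * np.arange(181) + 5000.0)
    out = cumulative_kuds(track, cr.default_windows(), KdeConfig(),
                          long_straight_mask)
    areas = out["kud95_km2"].to_numpy()
    assert (np.diff(areas) > 0).all()


def test_cumulative_areas_stable_for_stationary_cloud(long_straight_mask):
    rng = np.random.default_rng(10)
    track = _daily_track(50_000.0 + rng.normal(0, 500.0, 181))
    out = cumulative_kuds(track, cr.default_windows(), KdeConfig(),
                          long_straight_mask)
    areas = out["kud95_km2"].to_numpy()
    assert areas.max() / areas.min() < 1.15


def test_cumulative_idempotent_when_no_new_fixes(long_straight_mask):
    track = _daily_track(50_000.0 + 100.0 * np.arange(20))  # Sep only
    out = cumulative_kuds(track, cr.default_windows(), KdeConfig(),
                          long_straight_mask)
    areas = out["kud95_km2"].to_numpy()
    assert (areas == areas[0]).all()
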