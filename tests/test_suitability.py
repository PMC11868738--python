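"""Suitability-mask construction: extraction, percentiles, masks, regions."""

import numpy as np
import pytest

from nestpattern.geometry import PointSet
from nestpattern.suitability import (
    BinaryMask,
    RasterGrid,
    SuitabilityThresholds,
    combine_masks,
    extract_at_points,
    mask_to_region,
    mean_over_dates,
    overlap_fraction,
    percentile_thresholds,
    suitable_region_from_rasters,
    threshold_mask,
)


def grid(values, cell=10.0):
    values = np.asarray(values, float)
    return RasterGrid(values, xmin=0.0, ymax=values.shape[0] * cell, cell_size=cell)


def test_extract_at_points_cell_lookup_and_nodata():
    r = grid([[1, 2], [3, 4]])  # rows top-down: row 0 is y in (10, 20]
    vals = extract_at_points(r, PointSet([(5, 15), (15, 5)]))
    np.testing.assert_allclose(vals, [1.0, 4.0])
    r2 = grid([[np.nan, 2], [3, 4]])
    assert np.isnan(extract_at_points(r2, PointSet([(5, 15)]))[0])


def test_extract_outside_extent_warns_and_is_missing():
    r = grid([[1, 2], [3, 4]])
    with pytest.warns(UserWarning, match="outside raster extent"):
        vals = extract_at_points(r, PointSet([(100, 100), (5, 15)]))
    assert np.isnan(vals[0]) and vals[1] == 1.0


def test_extract_matches_manual_index_arithmetic(rng):
    vals = rng.normal(size=(7, 9))
    cell = 10.0
    r = RasterGrid(vals, xmin=100.0, ymax=500.0, cell_size=cell)
    xs = rng.uniform(100, 100 + 9 * cell, 10)
    ys = rng.uniform(500 - 7 * cell, 500, 10)
    out = extract_at_points(r, PointSet(np.column_stack([xs, ys])))
    for k in range(10):
        col = int((xs[k] - 100.0) // cell)
        row = int((500.0 - ys[k]) // cell)
        assert out[k] == vals[row, col]


def test_mean_over_dates_skips_missing():
    np.testing.assert_allclose(mean_over_dates([[1, 2], [3, 4]]), [2, 3])
    got = mean_over_dates([[1, np.nan], [3, 5]])
    np.testing.assert_allclose(got, [2, 5])
    assert np.isnan(mean_over_dates([[np.nan], [np.nan]])[0])
    with pytest.raises(ValueError):
        mean_over_dates([])
    with pytest.raises(ValueError):
        mean_over_dates([[1, 2], [1]])


def test_percentile_thresholds_linear_interpolation():
    t = percentile_thresholds([7.0] * 10)
    assert (t.low, t.high) == (7.0, 7.0)
    t = percentile_thresholds(np.arange(101.0), 5, 95)
    assert t.low == pytest.approx(5.0)
    assert t.high == pytest.approx(95.0)
    # linear interpolation between order statistics, computed by hand
    vals = np.array([1.0, 2.0, 4.0, 8.0])
    t = percentile_thresholds(vals, 25, 75)
    assert t.low == pytest.approx(1.75)   # 1 + 0.75*(2-1)
    assert t.high == pytest.approx(5.0)   # 4 + 0.25*(8-4)
    with pytest.raises(ValueError):
        percentile_thresholds([1.0])


def test_threshold_mask_inclusive_range_and_nodata():
    r = grid([[1, 5, 9]])
    m = threshold_mask(r, SuitabilityThresholds(2, 8))
    np.testing.assert_array_equal(m.values, [[False, True, False]])
    m_all = threshold_mask(r, SuitabilityThresholds(0, 100))
    assert m_all.values.all()
    m_edge = threshold_mask(r, SuitabilityThresholds(1, 9))
    assert m_edge.values.all()  # bounds are inclusive
    r_nd = grid([[np.nan, 5]])
    assert not threshold_mask(r_nd, SuitabilityThresholds(0, 10)).values[0, 0]


def test_threshold_mask_monotone_in_range(rng):
    r = grid(rng.normal(size=(12, 12)))
    narrow = threshold_mask(r, SuitabilityThresholds(-0.5, 0.5))
    wide = threshold_mask(r, SuitabilityThresholds(-1.5, 1.5))
    assert not (narrow.values & ~wide.values).any()  # widening never removes cells


def test_overlap_fraction_conventions():
    a = BinaryMask(np.array([[1, 1, 1, 1]], bool), 0, 10, 10)
    half = BinaryMask(np.array([[1, 1, 0, 0]], bool), 0, 10, 10)
    other = BinaryMask(np.array([[0, 0, 1, 1]], bool), 0, 10, 10)
    assert overlap_fraction(a, a) == 1.0
    assert overlap_fraction(half, other) == 0.0
    # contained mask: min-denominator gives 1, jaccard gives the area ratio
    assert overlap_fraction(a, half, "min") == 1.0
    assert overlap_fraction(half, a, "min") == 1.0  # symmetric
    assert overlap_fraction(a, half, "jaccard") == pytest.approx(0.5)
    with pytest.raises(ValueError):
        overlap_fraction(a, BinaryMask(np.zeros((1, 4), bool), 0, 10, 10))


def test_combine_masks_union_intersection_and_area_bounds(rng):
    comp_a = BinaryMask(np.array([[1, 0], [0, 1]], bool), 0, 20, 10)
    comp_b = BinaryMask(np.array([[0, 1], [1, 0]], bool), 0, 20, 10)
    assert combine_masks([comp_a, comp_b], "union").values.all()
    assert not combine_masks([comp_a, comp_b], "intersection").values.any()
    masks = [BinaryMask(rng.random((6, 6)) > 0.5, 0, 60, 10) for _ in range(3)]
    union = combine_masks(masks, "union")
    inter = combine_masks(masks, "intersection")
    assert union.area >= max(m.area for m in masks)
    assert inter.area <= min(m.area for m in masks)
    stack = np.stack([m.values for m in masks])
    np.testing.assert_array_equal(union.values, stack.any(axis=0))
    np.testing.assert_array_equal(inter.values, stack.all(axis=0))


def test_mask_to_region_area_conservation(rng):
    single = BinaryMask(np.array([[True]]), 0, 10, 10)
    assert mask_to_region(single).area == pytest.approx(100.0)
    block = BinaryMask(np.array([[True, True]]), 0, 10, 10)
    assert mask_to_region(block).area == pytest.approx(200.0)
    rand = BinaryMask(rng.random((15, 15)) > 0.6, 0, 150, 10)
    region = mask_to_region(rand)
    assert region.area == pytest.approx(rand.values.sum() * 100.0, rel=1e-9)
    with pytest.raises(ValueError):
        mask_to_region(BinaryMask(np.zeros((2, 2), bool), 0, 20, 10))


def test_ascii_grid_roundtrip(tmp_path, rng):
    vals = rng.normal(size=(5, 7))
    vals[0, 0] = np.nan
    r = RasterGrid(vals, xmin=12.5, ymax=300.0, cell_size=12.5)
    path = tmp_path / "r.asc"
    r.to_ascii(path)
    r2 = RasterGrid.from_ascii(path)
    assert r2.aligned_with(r)
    np.testing.assert_allclose(r2.values, r.values, rtol=1e-9, equal_nan=True)


def test_full_mask_pipeline_recovers_band(landscape, clustered_dataset):
    from nestpattern.synthetic import make_toy_rasters

    years = (2018, 2019, 2020)
    rasters = make_toy_rasters(landscape, years, n_dates=2, cell_size=50.0, seed=4)
    nests = {y: clustered_dataset.nests_by_year[y] for y in years}
    region, info = suitable_region_from_rasters(rasters, nests)
    true_area = landscape.region.area
    # the toy indices separate band from outside, so the derived area should
    # be close to the true suitable band
    assert abs(region.area - true_area) / true_area < 0.05
    for idx in ("ndvi", "sar"):
        assert info["indices"][idx]["min_overlap"] > 0.77
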