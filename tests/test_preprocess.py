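"""Compositing, regridding, land-cover aggregation, filtering, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegclim.grids import landcover_array, ndvi_dataset
from vegclim.preprocess import (
    PixelDataset,
    dominant_landcover,
    filter_valid_pixels,
    mvc_composite,
    regrid_mean,
    window_series,
)
from vegclim.synthetic import GridSpec, ResponseParams, generate_climate, generate_ndvi, inject_invalid


def _fine_grid(values):
    """(time, lat, lon) array -> 15-day NDVI dataset."""
    return ndvi_dataset(np.asarray(values, dtype=float), 1982, "15day")


class TestMvc:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((0.3, 0.5), 0.5),
            ((0.4, np.nan), 0.4),
            ((np.nan, np.nan), np.nan),
        ],
    )
    def test_monthly_maximum_with_missing(self, pair, expected):
        grid = _fine_grid(np.array(pair).reshape(2, 1, 1))
        out = mvc_composite(grid)["ndvi"].values[0, 0, 0]
        if np.isnan(expected):
            assert np.isnan(out)
        else:
            assert out == expected

    def test_odd_composite_count_rejected(self):
        grid = _fine_grid(np.zeros((3, 1, 1)))
        with pytest.raises(ValueError, match="odd"):
            mvc_composite(grid)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-0.9, 0.9), min_size=4, max_size=8).filter(lambda v: len(v) % 2 == 0))
    def test_commutes_with_monotone_rescaling(self, vals):
        arr = np.array(vals).reshape(-1, 1, 1)
        scale = lambda x: 0.5 * x + 0.1  # strictly increasing
        a = mvc_composite(_fine_grid(scale(arr)))["ndvi"].values
        b = scale(mvc_composite(_fine_grid(arr))["ndvi"].values)
        assert np.allclose(a, b, atol=1e-12)


class TestRegrid:
    def test_hand_computed_block_mean(self):
        block = np.array([[0.2, 0.4], [0.6, 0.8]]).reshape(1, 2, 2)
        out = regrid_mean(ndvi_dataset(block, 1982, "monthly"), 2)
        assert out["ndvi"].values[0, 0, 0] == pytest.approx(0.5, abs=1e-15)

    def test_factor_one_is_identity(self):
        grid = ndvi_dataset(np.random.default_rng(0).uniform(size=(3, 4, 4)), 1982, "monthly")
        out = regrid_mean(grid, 1)
        assert (out["ndvi"].values == grid["ndvi"].values).all()

    def test_all_missing_block_stays_missing(self):
        vals = np.full((1, 2, 2), np.nan)
        out = regrid_mean(ndvi_dataset(vals, 1982, "monthly"), 2)
        assert np.isnan(out["ndvi"].values).all()

    def test_preserves_global_mean_on_valid_grids(self, rng):
        vals = rng.uniform(0, 1, size=(5, 6, 6))
        out = regrid_mean(ndvi_dataset(vals, 1982, "monthly"), 3)
        assert out["ndvi"].values.mean() == pytest.approx(vals.mean(), abs=1e-12)

    def test_non_divisible_dimensions_rejected(self):
        grid = ndvi_dataset(np.zeros((1, 5, 6)), 1982, "monthly")
        with pytest.raises(ValueError, match="not divisible"):
            regrid_mean(grid, 2)


class TestDominantLandcover:
    def test_strict_majority(self):
        codes = np.full((6, 6), 3)
        codes[:4, :5] = 7  # 20 of 36 cells
        out = dominant_landcover(landcover_array(codes, 17), 6)
        assert out.values[0, 0] == 7

    def test_tie_breaks_to_lowest_code(self):
        codes = np.empty((6, 6), dtype=int)
        codes[:3] = 9
        codes[3:] = 3  # 18 vs 18
        out = dominant_landcover(landcover_array(codes, 17), 6)
        assert out.values[0, 0] == 3

    def test_factor_one_is_identity(self):
        codes = np.arange(1, 10).reshape(3, 3)
        out = dominant_landcover(landcover_array(codes, 17), 1)
        assert (out.values == codes).all()


class TestFilterValidPixels:
    def _grid(self, seed=0, fine_factor=1, n=(6, 6)):
        spec = GridSpec(n_lat=n[0], n_lon=n[1], fine_factor=fine_factor, n_years=34)
        params = ResponseParams()
        clim = generate_climate(spec, params, seed)
        fine, _ = generate_ndvi(clim, spec, params, seed)
        return spec, clim, fine

    def test_all_valid_yields_one_dataset_per_pixel(self):
        spec, clim, fine = self._grid()
        monthly = mvc_composite(fine)
        datasets = filter_valid_pixels(regrid_mean(monthly, 1), clim)
        assert len(datasets) == 36

    def test_invalidated_quarter_removed(self):
        spec, clim, fine = self._grid()
        bad = inject_invalid(fine, 0.25, seed=1)  # 9 of 36 pixels
        monthly = mvc_composite(bad)
        datasets = filter_valid_pixels(regrid_mean(monthly, 1), clim)
        assert len(datasets) == 27

    def test_single_missing_month_excludes_pixel(self):
        spec, clim, fine = self._grid()
        monthly = mvc_composite(fine)
        monthly["ndvi"].values[100, 2, 3] = np.nan
        datasets = filter_valid_pixels(monthly, clim)
        ids = {d.pixel_id for d in datasets}
        assert len(datasets) == 35 and (2 * 6 + 3) not in ids

    def test_empty_result_raises(self):
        spec, clim, fine = self._grid()
        monthly = mvc_composite(fine)
        monthly["ndvi"].values[0] = np.nan
        with pytest.raises(ValueError, match="no valid pixels"):
            filter_valid_pixels(monthly, clim)


class TestWindowing:
    def _dataset(self, n_months=408, train=264):
        rng = np.random.default_rng(0)
        return PixelDataset(
            pixel_id=0,
            lat_idx=0,
            lon_idx=0,
            temperature=rng.normal(10, 5, n_months),
            precipitation=rng.uniform(0, 100, n_months),
            ndvi=rng.uniform(0, 0.8, n_months),
            train_months=train,
        )

    def test_default_window_counts(self):
        train, val = window_series(self._dataset())
        assert train.n_windows == 259  # 264 - 6 + 1
        assert val.n_windows == 24  # 144 / 6

    def test_stride_six_on_training_split(self):
        train, _ = window_series(self._dataset(), train_stride=6)
        assert train.n_windows == 44  # 264 / 6

    def test_validation_tiles_without_gaps_or_overlap(self):
        ds = self._dataset()
        _, val = window_series(ds)
        assert val.tiles_exactly()
        covered = np.concatenate([np.arange(s, s + 6) for s in val.starts])
        assert (covered == np.arange(264, 408)).all()
        # targets reconstruct the validation series exactly
        assert (val.y.reshape(-1) == ds.ndvi[264:]).all()

    def test_no_window_crosses_split_boundary(self):
        train, val = window_series(self._dataset())
        assert train.starts.max() + 6 <= 264
        assert val.starts.min() >= 264

    def test_normalization_uses_train_statistics_only(self):
        ds = self._dataset()
        manual_mean = ds.temperature[:264].mean()
        assert ds.norm_mean[0] == pytest.approx(manual_mean, abs=1e-12)
        # perturbing validation months must not change the constants
        ds2 = self._dataset()
        ds2.temperature[300:] += 100.0
        recomputed = PixelDataset(
            pixel_id=0, lat_idx=0, lon_idx=0,
            temperature=ds2.temperature, precipitation=ds2.precipitation,
            ndvi=ds2.ndvi, train_months=264,
        )
        assert recomputed.norm_mean[0] == pytest.approx(manual_mean, abs=1e-12)

    def test_short_split_rejected(self):
        ds = self._dataset(n_months=12, train=8)
        with pytest.raises(ValueError, match="shorter"):
            window_series(ds)
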