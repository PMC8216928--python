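"""Generator contracts: determinism, analytic structure, invariants."""

import numpy as np
import pandas as pd
import pytest

from vegclim.synthetic import (
    GridSpec,
    ResponseParams,
    generate_climate,
    generate_landcover,
    generate_ndvi,
    inject_invalid,
    lagged_anomaly_z,
)


def det_params(**kw):
    base = dict(
        noise_sd=0.0,
        ar_coef=0.0,
        trend_per_year=0.0,
        temp_noise_sd=0.0,
        precip_noise_sd=0.0,
        composite_noise_sd=0.0,
        fine_hetero_sd=0.0,
    )
    base.update(kw)
    return ResponseParams(**base)


class TestGenerateClimate:
    def test_no_trend_no_noise_gives_identical_julys(self):
        spec = GridSpec(n_lat=2, n_lon=3, n_years=10)
        clim = generate_climate(spec, det_params(), seed=0)
        t = clim["temperature"].values
        julys = t[6::12]
        assert np.allclose(julys, julys[0], atol=1e-12)

    def test_linear_trend_gives_analytic_pentad_difference(self):
        # 0.05 degC/yr over 1982-2015: mean(2011-15) - mean(1982-86)
        # = 0.05 * (2013 - 1984) = 1.45 degC at every pixel
        spec = GridSpec(n_lat=2, n_lon=2, n_years=34)
        clim = generate_climate(spec, det_params(trend_per_year=0.05), seed=0)
        t = clim["temperature"].values
        delta = t[-60:].mean(axis=0) - t[:60].mean(axis=0)
        assert np.allclose(delta, 1.45, atol=1e-9)

    def test_same_seed_bit_identical(self):
        spec = GridSpec(n_lat=2, n_lon=2, n_years=3)
        a = generate_climate(spec, ResponseParams(), seed=42)
        b = generate_climate(spec, ResponseParams(), seed=42)
        assert (a["temperature"].values == b["temperature"].values).all()
        assert (a["precipitation"].values == b["precipitation"].values).all()

    def test_precipitation_nonnegative(self):
        spec = GridSpec(n_lat=3, n_lon=3, n_years=5)
        clim = generate_climate(
            spec, ResponseParams(precip_noise_sd=200.0), seed=3
        )
        assert (clim["precipitation"].values >= 0).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(n_lat=0, n_lon=4)


class TestGenerateNdvi:
    def test_no_coupling_no_noise_is_pure_seasonal_cycle(self):
        spec = GridSpec(n_lat=1, n_lon=1, n_years=5)
        params = det_params(w_T=0.0, w_P=0.0)
        clim = generate_climate(spec, params, seed=0)
        fine, _ = generate_ndvi(clim, spec, params, seed=0)
        v = fine["ndvi"].values[:, 0, 0]
        years = v.reshape(5, 24)
        assert np.allclose(years, years[0], atol=1e-12)

    def test_temperature_only_pixel_tracks_temperature_not_precipitation(self):
        spec = GridSpec(n_lat=1, n_lon=1, fine_factor=1, n_years=30)
        params = ResponseParams(
            w_T=0.3,
            w_P=0.0,
            noise_sd=0.001,
            ar_coef=0.0,
            season_amp=0.0,
            trend_per_year=0.0,
            composite_noise_sd=0.0,
            fine_hetero_sd=0.0,
        )
        clim = generate_climate(spec, params, seed=5)
        fine, _ = generate_ndvi(clim, spec, params, seed=5)
        monthly = fine["ndvi"].values[::2, 0, 0]  # composites are equal here
        ann_v = monthly.reshape(30, 12).mean(axis=1)
        z_t = lagged_anomaly_z(clim["temperature"].values[:, 0, 0], 3)
        z_p = lagged_anomaly_z(clim["precipitation"].values[:, 0, 0], 3)
        r_t = np.corrcoef(ann_v, z_t.reshape(30, 12).mean(axis=1))[0, 1]
        r_p = np.corrcoef(ann_v, z_p.reshape(30, 12).mean(axis=1))[0, 1]
        assert r_t > 0.9 > abs(r_p)

    def test_values_inside_unit_interval(self):
        spec = GridSpec(n_lat=2, n_lon=2, n_years=4)
        params = ResponseParams(noise_sd=0.5, w_T=1.0, w_P=1.0)
        clim = generate_climate(spec, params, seed=9)
        fine, _ = generate_ndvi(clim, spec, params, seed=9)
        v = fine["ndvi"].values
        assert (v > -1).all() and (v < 1).all()

    def test_truth_labels_match_weights(self):
        spec = GridSpec(n_lat=2, n_lon=2, n_years=2)
        w_t = np.array([[0.2, 0.0], [0.1, 0.0]])
        w_p = np.array([[0.0, 0.2], [0.1, 0.0]])
        params = ResponseParams(w_T=w_t, w_P=w_p)
        clim = generate_climate(spec, params, seed=0)
        _, truth = generate_ndvi(clim, spec, params, seed=0)
        assert list(truth.table["sens_class"]) == [
            "temperature",
            "precipitation",
            "both",
            "both",  # w_T = w_P = 0 responds to neither alone
        ]

    def test_mismatched_climate_rejected(self):
        spec = GridSpec(n_lat=2, n_lon=2, n_years=2)
        clim = generate_climate(spec, ResponseParams(), seed=0)
        with pytest.raises(ValueError):
            generate_ndvi(clim, GridSpec(n_lat=3, n_lon=2, n_years=2), ResponseParams(), seed=0)


class TestLandcoverAndInvalidation:
    def test_codes_in_range_and_deterministic(self):
        spec = GridSpec(n_lat=2, n_lon=2, n_years=1)
        a = generate_landcover(spec, n_classes=5, seed=7)
        b = generate_landcover(spec, n_classes=5, seed=7)
        assert (a.values == b.values).all()
        assert set(np.unique(a.values)) <= set(range(1, 6))

    def test_single_block_single_class(self):
        spec = GridSpec(n_lat=1, n_lon=1, fine_factor=4, n_years=1)
        lc = generate_landcover(spec, n_classes=2, seed=0, block_size=4)
        assert len(np.unique(lc.values)) == 1

    def test_too_few_classes_rejected(self):
        spec = GridSpec(n_lat=1, n_lon=1, n_years=1)
        with pytest.raises(ValueError):
            generate_landcover(spec, n_classes=1, seed=0)

    def test_inject_invalid_counts_and_determinism(self):
        spec = GridSpec(n_lat=2, n_lon=2, fine_factor=5, n_years=1)
        params = ResponseParams()
        clim = generate_climate(spec, params, seed=0)
        fine, _ = generate_ndvi(clim, spec, params, seed=0)
        # 100 fine pixels, fraction 0.25 -> exactly 25 all-NaN series
        out = inject_invalid(fine, 0.25, seed=1)
        bad = np.isnan(out["ndvi"].values).all(axis=0)
        assert bad.sum() == 25
        out2 = inject_invalid(fine, 0.25, seed=1)
        assert (np.isnan(out2["ndvi"].values) == np.isnan(out["ndvi"].values)).all()
        # fraction 0 is the identity
        same = inject_invalid(fine, 0.0, seed=1)
        assert (same["ndvi"].values == fine["ndvi"].values).all()
        with pytest.raises(ValueError):
            inject_invalid(fine, 1.0, seed=1)


class TestAnomalyTransform:
    def test_constant_series_maps_to_zero(self):
        assert (lagged_anomaly_z(np.full(48, 5.0), 3) == 0).all()

    def test_unit_variance_after_standardization(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1200)
        z = lagged_anomaly_z(x, 3)
        assert z.std() == pytest.approx(1.0)
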