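import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pixphen.image_io import MultiChannelImage
from pixphen.preprocessing import (
    PixelTable,
    apply_percentile_norm,
    concat_tables,
    extract_pixels,
    fit_percentile_norm,
    normalize_pixels,
    smooth_channels,
    subsample_pixels,
)

from conftest import make_pixel_table


class TestSmoothChannels:
    def test_constant_channel_unchanged(self):
        image = MultiChannelImage("f", ["a"], np.full((1, 32, 32), 3.7))
        out = smooth_channels(image, sigma=2.0)
        assert np.allclose(out.data, 3.7, atol=1e-12)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        image = MultiChannelImage("f", ["a"], rng.uniform(0, 5, (1, 16, 16)))
        assert smooth_channels(image, 0.0) is image

    def test_impulse_matches_direct_kernel_convolution(self):
        # independent oracle: evaluate the truncated discrete Gaussian directly
        sigma = 2.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kern_1d = np.exp(-0.5 * (x / sigma) ** 2)
        kern_1d /= kern_1d.sum()
        kern_2d = np.outer(kern_1d, kern_1d)

        img = np.zeros((1, 64, 64))
        img[0, 32, 32] = 1.0
        out = smooth_channels(MultiChannelImage("f", ["a"], img), sigma).data[0]
        window = out[32 - radius : 32 + radius + 1, 32 - radius : 32 + radius + 1]
        assert np.allclose(window, kern_2d, atol=1e-6)

    def test_negative_sigma_rejected(self):
        image = MultiChannelImage("f", ["a"], np.zeros((1, 8, 8)))
        with pytest.raises(ValueError):
            smooth_channels(image, -1.0)


class TestExtractPixels:
    def test_all_zero_image_empty_table(self):
        table = extract_pixels(MultiChannelImage("f", ["a", "b"], np.zeros((2, 4, 4))))
        assert table.n_pixels == 0

    def test_one_zero_pixel_excluded(self):
        data = np.ones((2, 2, 2))
        data[:, 1, 1] = 0
        table = extract_pixels(MultiChannelImage("f", ["a", "b"], data))
        assert table.n_pixels == 3
        assert (1, 1) not in set(zip(table.coords["row"], table.coords["col"]))

    def test_matches_brute_force_scan_with_mask(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 1, (3, 20, 20)) * (rng.random((3, 20, 20)) > 0.4)
        mask = np.zeros((20, 20), bool)
        mask[:, :10] = True
        image = MultiChannelImage("f", ["a", "b", "c"], data)
        table = extract_pixels(image, region_mask=mask)

        expected = set()
        for r in range(20):
            for c in range(20):
                if mask[r, c] and data[:, r, c].any():
                    expected.add((r, c))
        assert set(zip(table.coords["row"], table.coords["col"])) == expected
        for r, c, vals in zip(table.coords["row"], table.coords["col"], table.values):
            assert np.array_equal(vals, data[:, r, c])

    def test_positivity_filter_is_strict(self):
        data = np.zeros((2, 1, 3))
        data[0] = [[0.0, 0.5, 1.0]]
        data[1] = [[1.0, 1.0, 1.0]]
        image = MultiChannelImage("f", ["SMA", "other"], data)
        table = extract_pixels(image, positivity_filter=("SMA", 0.5))
        assert list(table.coords["col"]) == [2]

    def test_mask_dimension_mismatch(self):
        image = MultiChannelImage("f", ["a"], np.ones((1, 4, 4)))
        with pytest.raises(ValueError, match="mask"):
            extract_pixels(image, region_mask=np.ones((5, 5), bool))


class TestNormalizePixels:
    def test_symmetric_row(self):
        table = PixelTable(
            pd.DataFrame({"fov": ["f"], "row": [0], "col": [0]}),
            np.array([[2.0, 2.0]]), ["a", "b"], stage="smoothed",
        )
        assert np.allclose(normalize_pixels(table).values, [[0.5, 0.5]])

    def test_one_hot_row_unchanged(self):
        table = PixelTable(
            pd.DataFrame({"fov": ["f"], "row": [0], "col": [0]}),
            np.array([[1.0, 0.0, 0.0]]), ["a", "b", "c"], stage="smoothed",
        )
        assert np.allclose(normalize_pixels(table).values, [[1, 0, 0]])

    def test_random_rows_sum_to_one(self):
        table = make_pixel_table(n_pixels=1000, n_markers=5, seed=1)
        out = normalize_pixels(table)
        assert np.all(np.abs(out.values.sum(axis=1) - 1) < 1e-9)
        assert out.stage == "pixel_normalized"

    def test_all_zero_row_rejected(self):
        table = PixelTable(
            pd.DataFrame({"fov": ["f"], "row": [0], "col": [0]}),
            np.array([[0.0, 0.0]]), ["a", "b"], stage="smoothed",
        )
        with pytest.raises(ValueError, match="all-zero"):
            normalize_pixels(table)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_property_row_sums(self, seed):
        table = make_pixel_table(n_pixels=50, n_markers=3, seed=seed)
        assert np.all(np.abs(normalize_pixels(table).values.sum(axis=1) - 1) < 1e-9)


class TestPercentileNorm:
    def test_constant_marker_divisor(self):
        table = make_pixel_table(n_pixels=100, n_markers=2, seed=2, stage="pixel_normalized")
        table.values[:, 0] = 0.4
        params = fit_percentile_norm(table)
        assert params.per_marker_divisor[0] == pytest.approx(0.4)
        out = apply_percentile_norm(table, params)
        assert np.allclose(out.values[:, 0], 1.0)

    def test_matches_sort_and_interpolate_oracle(self):
        values = np.arange(1.0, 1001.0)
        table = PixelTable(
            pd.DataFrame({"fov": "f", "row": np.arange(1000), "col": 0}),
            values[:, None], ["a"], stage="pixel_normalized",
        )
        params = fit_percentile_norm(table, quantile=0.999)
        # oracle: linear interpolation between order statistics
        v = np.sort(values)
        pos = 0.999 * (len(v) - 1)
        lo = int(np.floor(pos))
        expected = v[lo] + (pos - lo) * (v[lo + 1] - v[lo])
        assert params.per_marker_divisor[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_marker_error_names_it(self):
        table = make_pixel_table(n_pixels=50, n_markers=2, seed=3, stage="pixel_normalized")
        table.values[:, 1] = 0.0
        with pytest.raises(ValueError, match="m1"):
            fit_percentile_norm(table)

    def test_unit_divisors_identity(self):
        from pixphen.preprocessing import NormalizationParams

        table = make_pixel_table(n_pixels=20, n_markers=3, seed=4, stage="pixel_normalized")
        params = NormalizationParams(["m0", "m1", "m2"], np.ones(3))
        out = apply_percentile_norm(table, params)
        assert np.array_equal(out.values, table.values)
        assert out.stage == "fully_normalized"

    def test_simple_arithmetic(self):
        from pixphen.preprocessing import NormalizationParams

        table = PixelTable(
            pd.DataFrame({"fov": ["f"], "row": [0], "col": [0]}),
            np.array([[0.5, 0.5]]), ["a", "b"], stage="pixel_normalized",
        )
        out = apply_percentile_norm(table, NormalizationParams(["a", "b"], [0.5, 1.0]))
        assert np.allclose(out.values, [[1.0, 0.5]])

    def test_post_normalization_quantile_is_one(self):
        table = make_pixel_table(n_pixels=5000, n_markers=4, seed=5, stage="pixel_normalized")
        params = fit_percentile_norm(table)
        out = apply_percentile_norm(table, params)
        assert np.allclose(np.quantile(out.values, 0.999, axis=0), 1.0, atol=1e-6)

    def test_marker_set_mismatch(self):
        from pixphen.preprocessing import NormalizationParams

        table = make_pixel_table(n_pixels=10, n_markers=2, seed=6, stage="pixel_normalized")
        with pytest.raises(ValueError, match="marker set"):
            apply_percentile_norm(table, NormalizationParams(["x", "y"], [1.0, 1.0]))

    def test_params_json_round_trip(self, tmp_path):
        from pixphen.preprocessing import NormalizationParams

        table = make_pixel_table(n_pixels=100, n_markers=3, seed=7, stage="pixel_normalized")
        params = fit_percentile_norm(table)
        params.to_json(tmp_path / "p.json")
        loaded = NormalizationParams.from_json(tmp_path / "p.json")
        assert loaded.marker_names == params.marker_names
        assert np.allclose(loaded.per_marker_divisor, params.per_marker_divisor)


class TestSubsample:
    def test_fraction_one_returns_all(self):
        table = make_pixel_table(100)
        assert subsample_pixels(table, 1.0, seed=0) is table

    def test_exact_cardinality_and_distinct(self):
        table = make_pixel_table(1000)
        out = subsample_pixels(table, 0.1, seed=1)
        assert out.n_pixels == 100
        assert not out.coords.duplicated(["fov", "row", "col"]).any()

    def test_determinism(self):
        table = make_pixel_table(500)
        a = subsample_pixels(table, 0.3, seed=9)
        b = subsample_pixels(table, 0.3, seed=9)
        assert np.array_equal(a.values, b.values)
        assert a.coords.equals(b.coords)

    def test_empty_table_rejected(self):
        table = extract_pixels(MultiChannelImage("f", ["a"], np.zeros((1, 4, 4))))
        with pytest.raises(ValueError, match="empty"):
            subsample_pixels(table, 0.5, seed=0)


class TestScaleInvariance:
    def test_pixel_normalized_rows_invariant_to_fov_scaling(self, sig3):
        from pixphen import NoiseConfig, simulate_fov

        image, _, _ = simulate_fov(
            sig3, 64, 64, 10,
            noise=NoiseConfig(poisson_scale=0.0, dropout_prob=0.0), seed=6,
        )
        scaled = MultiChannelImage(image.fov_id, image.marker_names, image.data * 7.3)
        a = normalize_pixels(extract_pixels(image))
        b = normalize_pixels(extract_pixels(scaled))
        assert a.coords.equals(b.coords)
        assert np.allclose(a.values, b.values, atol=1e-12)


def test_concat_pools_fovs(sig3, noisy_dataset):
    tables = [extract_pixels(noisy_dataset[f][0]) for f in noisy_dataset]
    pooled = concat_tables(tables)
    assert pooled.n_pixels == sum(t.n_pixels for t in tables)
    assert set(pooled.coords["fov"]) == set(noisy_dataset)
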