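import numpy as np
import pytest
from hypothesis import given, strategies as st

from lcoratio import (
    FilterSettings,
    background_mask,
    gaussian_cutoff,
    genotype_preset,
    heatmap_data,
    image_set_mean,
    pooled_density,
    ratio_matrix,
    render_cube,
    violin_data,
)
from lcoratio.whole_image_analysis import GENOTYPE_FILTER_DEFAULTS, RatioMatrix


def loop_mean_std(matrix):
    """Two-pass loop oracle for the pixel mean and population sigma."""
    total = 0.0
    n = 0
    for row in matrix:
        for x in row:
            total += x
            n += 1
    mean = total / n
    ss = 0.0
    for row in matrix:
        for x in row:
            ss += (x - mean) ** 2
    return mean, (ss / n) ** 0.5


class TestGaussianCutoff:
    def test_hand_case(self):
        mu, sigma, cutoff = gaussian_cutoff(np.array([[0.0, 0.0], [10.0, 10.0]]), k=0)
        assert (mu, sigma, cutoff) == (5.0, 5.0, 5.0)

    def test_k_zero_cutoff_is_mean(self, rng):
        mat = rng.uniform(0, 9, (20, 20))
        _, _, cutoff = gaussian_cutoff(mat, k=0)
        assert cutoff == pytest.approx(mat.mean())

    def test_matches_loop_oracle(self, rng):
        mat = rng.uniform(0, 100, (30, 30))
        mu, sigma, cutoff = gaussian_cutoff(mat, k=2.5)
        mu_o, sigma_o = loop_mean_std(mat)
        assert mu == pytest.approx(mu_o, rel=1e-12)
        assert sigma == pytest.approx(sigma_o, rel=1e-12)
        assert cutoff == pytest.approx(mu_o + 2.5 * sigma_o, rel=1e-12)

    def test_constant_matrix_cutoff_is_mean(self):
        mu, sigma, cutoff = gaussian_cutoff(np.full((5, 5), 7.0), k=3)
        assert sigma == 0.0 and cutoff == mu == 7.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            gaussian_cutoff(np.empty((0, 0)), k=1)


class TestBackgroundMask:
    def test_infinite_multipliers_keep_everything(self, rng):
        low = rng.uniform(0, 10, (16, 16))
        high = rng.uniform(0, 10, (16, 16))
        mask = background_mask(low, high,
                               FilterSettings(k_upper_low=np.inf,
                                              k_lower_high=-np.inf))
        assert mask.all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            background_mask(np.zeros((4, 4)), np.zeros((4, 5)), FilterSettings())

    def test_saturated_artifact_pixel_excluded(self, rng):
        """Dark field plus one saturated 500 nm pixel: the bright-noise
        cutoff removes the artifact by hand-checkable arithmetic."""
        low = rng.normal(5.0, 0.5, (64, 64)).clip(0)
        high = rng.normal(20.0, 1.0, (64, 64)).clip(0)
        low[10, 10] = 5000.0
        settings = FilterSettings(k_upper_low=3.0, k_lower_high=-np.inf)
        mu, sigma, cutoff = gaussian_cutoff(low, settings.k_upper_low)
        assert cutoff < 5000.0  # the artifact sits above the reference interval
        mask = background_mask(low, high, settings)
        assert not mask[10, 10]
        assert mask.sum() == 64 * 64 - 1

    def test_default_filter_keeps_mostly_plaque_pixels(self, grid):
        purities = []
        for seed in range(2):
            scene = genotype_preset("APPPS1-like", seed=seed)
            cube, truth = render_cube(scene, grid, seed=seed)
            mask = background_mask(cube.plane(500), cube.plane(540),
                                   GENOTYPE_FILTER_DEFAULTS["APPPS1-like"])
            purities.append((mask & (truth.label_map > 0)).sum() / mask.sum())
        assert min(purities) >= 0.9

    def test_monotone_in_upper_low(self, rng):
        low = rng.uniform(0, 100, (32, 32))
        high = rng.uniform(0, 100, (32, 32))
        kept = [
            background_mask(low, high, FilterSettings(k_upper_low=k,
                                                      k_lower_high=-np.inf))
            for k in (2.0, 1.0, 0.0, -1.0)
        ]
        for bigger, smaller in zip(kept, kept[1:]):
            assert not (smaller & ~bigger).any()  # decreasing k never adds pixels

    def test_monotone_in_lower_high(self, rng):
        low = rng.uniform(0, 100, (32, 32))
        high = rng.uniform(0, 100, (32, 32))
        kept = [
            background_mask(low, high, FilterSettings(k_upper_low=np.inf,
                                                      k_lower_high=k))
            for k in (-1.0, 0.0, 1.0, 2.0)
        ]
        for bigger, smaller in zip(kept, kept[1:]):
            assert not (smaller & ~bigger).any()  # increasing k never adds pixels


class TestRatioMatrix:
    def test_constant_ratio(self):
        high = np.full((8, 8), 3.0)
        rm = ratio_matrix(2 * high, high)
        assert rm.mask.all()
        assert (rm.values == 2.0).all()

    def test_matches_loop_oracle(self, rng):
        low = rng.uniform(0, 50, (20, 20))
        high = rng.uniform(0.1, 50, (20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.3
        rm = ratio_matrix(low, high, mask)
        for r in range(20):
            for c in range(20):
                if mask[r, c]:
                    assert rm.values[r, c] == pytest.approx(
                        low[r, c] / high[r, c], rel=1e-12
                    )
                assert rm.mask[r, c] == mask[r, c]

    def test_nonpositive_denominator_removed_from_mask(self):
        low = np.ones((4, 4))
        high = np.ones((4, 4))
        high[0, 0] = 0.0
        rm = ratio_matrix(low, high)
        assert not rm.mask[0, 0]
        assert rm.n_kept == 15

    def test_empty_mask_is_valid(self):
        rm = ratio_matrix(np.ones((4, 4)), np.ones((4, 4)),
                          np.zeros((4, 4), dtype=bool))
        assert rm.n_kept == 0
        assert violin_data([rm]).size == 0

    @given(gain=st.floats(0.01, 1000))
    def test_gain_invariance_of_values_and_mask(self, gain):
        rng = np.random.default_rng(5)
        low = rng.uniform(0, 50, (16, 16))
        high = rng.uniform(0.1, 50, (16, 16))
        settings = FilterSettings(k_upper_low=1.0, k_lower_high=-0.5)
        base_mask = background_mask(low, high, settings)
        base = ratio_matrix(low, high, base_mask)
        scaled_mask = background_mask(gain * low, gain * high, settings)
        scaled = ratio_matrix(gain * low, gain * high, scaled_mask)
        np.testing.assert_array_equal(base.mask, scaled.mask)
        np.testing.assert_allclose(
            scaled.values[scaled.mask], base.values[base.mask], rtol=1e-9
        )


class TestHeatmap:
    def test_full_mask_identity(self, rng):
        high = rng.uniform(1, 2, (8, 8))
        rm = ratio_matrix(rng.uniform(0, 1, (8, 8)), high)
        np.testing.assert_array_equal(heatmap_data(rm), rm.values)

    def test_masked_pixels_carry_sentinel(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        rm = ratio_matrix(np.ones((4, 4)), np.full((4, 4), 2.0), mask)
        out = heatmap_data(rm)
        assert out[1, 1] == 0.5
        assert np.isnan(out[mask == False]).all()  # noqa: E712

    def test_round_trip_with_ratio_matrix(self, rng):
        high = rng.uniform(1, 2, (8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.5
        rm = ratio_matrix(rng.uniform(0, 1, (8, 8)), high, mask)
        out = heatmap_data(rm)
        recovered = RatioMatrix(values=np.nan_to_num(out), mask=~np.isnan(out))
        np.testing.assert_array_equal(recovered.mask, rm.mask)
        np.testing.assert_array_equal(recovered.values[recovered.mask],
                                      rm.values[rm.mask])


class TestPooledDensity:
    def test_single_pixel_peaks_at_value(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        rm = ratio_matrix(np.full((2, 2), 3.0), np.full((2, 2), 2.0), mask)
        curve = pooled_density([rm])
        assert curve.mode == pytest.approx(1.5, abs=1e-2)

    def test_duplicate_images_do_not_change_curve(self, rng):
        # At a fixed bandwidth the pooled KDE depends only on the value
        # distribution, so duplicating an image is a no-op.  (Silverman's
        # rule shrinks with pixel count, so it is overridden here.)
        high = rng.uniform(1, 2, (16, 16))
        rm = ratio_matrix(rng.uniform(0.5, 1.5, (16, 16)), high)
        one = pooled_density([rm], bandwidth=0.05)
        two = pooled_density([rm, rm], bandwidth=0.05)
        np.testing.assert_allclose(two.density, one.density, rtol=1e-9)

    def test_normalization(self, rng):
        high = rng.uniform(1, 2, (16, 16))
        rm = ratio_matrix(rng.uniform(0.5, 1.5, (16, 16)), high)
        curve = pooled_density([rm])
        assert np.trapezoid(curve.density, curve.ratio) == pytest.approx(1.0, abs=1e-3)

    def test_zero_kept_pixels_rejected(self):
        rm = ratio_matrix(np.ones((2, 2)), np.ones((2, 2)),
                          np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="no kept pixels"):
            pooled_density([rm])


class TestImageSetMean:
    def test_constant_matrix(self):
        rm = ratio_matrix(np.full((4, 4), 6.0), np.full((4, 4), 3.0))
        mean, n = image_set_mean([rm])
        assert mean == 2.0 and n == 16

    def test_pooled_equals_count_weighted_mean_of_images(self, rng):
        rms = []
        for _ in range(3):
            mask = rng.uniform(size=(10, 10)) > 0.4
            rms.append(ratio_matrix(rng.uniform(0, 5, (10, 10)),
                                    rng.uniform(1, 5, (10, 10)), mask))
        pooled, n = image_set_mean(rms)
        weighted = sum(rm.kept_values.sum() for rm in rms) / sum(
            rm.n_kept for rm in rms
        )
        assert pooled == pytest.approx(weighted, rel=1e-12)
        assert n == sum(rm.n_kept for rm in rms)

    def test_matches_loop_oracle(self, rng):
        mask = rng.uniform(size=(12, 12)) > 0.5
        low = rng.uniform(0, 5, (12, 12))
        high = rng.uniform(1, 5, (12, 12))
        rm = ratio_matrix(low, high, mask)
        total, n = 0.0, 0
        for r in range(12):
            for c in range(12):
                if mask[r, c]:
                    total += low[r, c] / high[r, c]
                    n += 1
        mean, n_got = image_set_mean([rm])
        assert mean == pytest.approx(total / n, rel=1e-12)
        assert n_got == n
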