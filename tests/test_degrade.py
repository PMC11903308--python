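"""Degradation primitives: statistical laws, composition, sampling frequencies."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from cellrestore.degrade import (
    BETA_DEFAULTS,
    DegenerateIntensityError,
    DegradationSpec,
    DegradeConfig,
    add_poisson_noise,
    apply_degradation,
    decimate,
    downsample_upsample,
    gaussian_blur,
    normalize_percentile,
    sample_degradation,
    sample_poisson_scale,
)
from cellrestore.simcells import generate_cell_image


class TestNormalizePercentile:
    def test_ramp_maps_percentiles_to_unit_interval(self):
        img = np.linspace(0, 100, 10_000).reshape(100, 100)
        out = normalize_percentile(img)
        # the clip at 0 nudges the output's 1st percentile up by at most one
        # interpolation step, hence the slightly looser tolerance there
        assert np.percentile(out, 1) == pytest.approx(0.0, abs=1e-5)
        assert np.percentile(out, 99) == pytest.approx(1.0, abs=1e-6)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateIntensityError):
            normalize_percentile(np.full((32, 32), 3.0))

    def test_matches_direct_quantile_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.lognormal(0, 1, size=(64, 64))
        q01, q99 = np.quantile(img, [0.01, 0.99])
        expected = np.clip((img - q01) / (q99 - q01), 0, None)
        assert normalize_percentile(img) == pytest.approx(expected.astype(np.float32), abs=1e-5)

    def test_no_upper_clip(self):
        img = np.linspace(0, 100, 10_000)
        assert normalize_percentile(img).max() > 1.0


class TestPoissonNoise:
    @pytest.mark.parametrize("s", [1.0, 10.0, 100.0])
    def test_mean_and_variance_laws(self, s):
        """Poisson(s*I)/s has mean I and variance I/s."""
        n = 100_000
        img = np.ones(n)
        out = add_poisson_noise(img, s, np.random.default_rng(123))
        sigma_mean = np.sqrt(1.0 / s / n)
        assert abs(out.mean() - 1.0) < 3 * sigma_mean
        assert out.var() == pytest.approx(1.0 / s, rel=0.10)

    def test_high_count_limit_is_identity(self):
        img = np.random.default_rng(1).random((64, 64))
        out = add_poisson_noise(img, 1e6, np.random.default_rng(2))
        assert np.max(np.abs(out - img)) < 0.02

    def test_zero_image_stays_zero(self):
        out = add_poisson_noise(np.zeros((16, 16)), 5.0, np.random.default_rng(0))
        assert np.all(out == 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            add_poisson_noise(np.array([-0.1, 0.5]), 1.0, np.random.default_rng(0))


class TestPoissonScale:
    def test_gamma_rate_parameterization_mean(self):
        """s ~ Gamma(shape=4, rate=beta) has mean 4/beta."""
        rng = np.random.default_rng(7)
        for beta in (0.7, 0.1):
            draws = [sample_poisson_scale(rng, 4.0, beta) for _ in range(100_000)]
            assert np.mean(draws) == pytest.approx(4.0 / beta, rel=0.03)

    def test_seeded_draws_identical(self):
        a = sample_poisson_scale(np.random.default_rng(3))
        b = sample_poisson_scale(np.random.default_rng(3))
        assert a == b

    def test_mode_defaults(self):
        assert BETA_DEFAULTS["denoise"] == 0.7
        assert BETA_DEFAULTS["deblur"] == 0.1
        assert BETA_DEFAULTS["upsample"] == 0.03

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            sample_poisson_scale(np.random.default_rng(0), alpha=0.0)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        assert np.array_equal(gaussian_blur(img, 0, 0), img.astype(np.float32))

    def test_impulse_response_recovers_sigma(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = gaussian_blur(img, 2.0, 2.0)
        x = np.arange(65, dtype=float)
        profile = out[32]

        def g(x, a, mu, sigma):
            return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

        popt, _ = curve_fit(g, x, profile, p0=(profile.max(), 32, 3))
        assert abs(popt[2]) == pytest.approx(2.0, rel=0.05)

    def test_constant_preserved(self):
        img = np.full((32, 32), 0.7)
        assert gaussian_blur(img, 3, 3) == pytest.approx(img, abs=1e-6)

    def test_total_intensity_conserved_for_interior_support(self):
        img = np.zeros((64, 64))
        img[24:40, 24:40] = np.random.default_rng(0).random((16, 16))
        out = gaussian_blur(img, 2, 2)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-4)


class TestDownsampleUpsample:
    def test_constant_identity_without_pre_blur(self):
        img = np.full((64, 64), 0.5)
        out = downsample_upsample(img, 4, pre_blur_sigma=0)
        assert out == pytest.approx(img, abs=1e-6)

    def test_shape_contract(self):
        img = np.random.default_rng(0).random((64, 64))
        assert decimate(img, 4).shape == (16, 16)
        assert downsample_upsample(img, 4).shape == (64, 64)

    def test_decimation_index_set_oracle(self):
        img = np.arange(64 * 64, dtype=float).reshape(64, 64)
        for f in (2, 3, 4):
            idx = np.arange(0, 64, f)
            assert np.array_equal(decimate(img, f), img[np.ix_(idx, idx)])

    def test_factor_too_large_raises(self):
        with pytest.raises(ValueError):
            downsample_upsample(np.zeros((32, 32)), 10)


class TestSampleDegradation:
    def test_noise_fires_eighty_percent(self):
        cfg = DegradeConfig(mode="denoise")
        rng = np.random.default_rng(0)
        n = 10_000
        hits = sum(sample_degradation(cfg, 30, rng).apply_noise for _ in range(n))
        sigma = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - 0.8) < 3 * sigma

    def test_mode_all_splits_in_thirds(self):
        cfg = DegradeConfig(mode="all")
        rng = np.random.default_rng(1)
        n = 30_000
        counts = {"denoise": 0, "deblur": 0, "upsample": 0}
        for _ in range(n):
            counts[sample_degradation(cfg, 30, rng).mode] += 1
        sigma = np.sqrt((1 / 3) * (2 / 3) / n)
        for mode in counts:
            assert abs(counts[mode] / n - 1 / 3) < 3 * sigma

    def test_fixed_seed_gives_identical_spec(self):
        cfg = DegradeConfig(mode="all")
        a = sample_degradation(cfg, 30, np.random.default_rng(9))
        b = sample_degradation(cfg, 30, np.random.default_rng(9))
        assert a == b

    def test_blur_sigma_scales_with_diameter(self):
        cfg = DegradeConfig(mode="deblur", p_blur=1.0, p_noise=0.0)
        sig30 = [sample_degradation(cfg, 30, np.random.default_rng(s)).blur_sigma_y
                 for s in range(50)]
        sig15 = [sample_degradation(cfg, 15, np.random.default_rng(s)).blur_sigma_y
                 for s in range(50)]
        assert np.allclose(np.array(sig15) * 2, sig30)


class TestApplyDegradation:
    def test_all_flags_off_equals_normalize(self):
        li = generate_cell_image(5, 16, (64, 64), seed=2)
        out = apply_degradation(li, DegradationSpec(mode="denoise"))
        assert np.array_equal(out, normalize_percentile(normalize_percentile(li.image)))

    def test_noise_only_reproducible(self):
        li = generate_cell_image(5, 16, (64, 64), seed=2)
        spec = DegradationSpec(mode="denoise", apply_noise=True, poisson_scale=5.0)
        a = apply_degradation(li, spec, np.random.default_rng(4))
        b = apply_degradation(li, spec, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_masks_never_touched(self):
        li = generate_cell_image(5, 16, (64, 64), seed=2)
        before = li.masks.copy()
        spec = DegradationSpec(mode="upsample", apply_noise=True, poisson_scale=3.0,
                               apply_downsample=True, ds_factor=2, pre_blur_sigma=0.8)
        apply_degradation(li, spec, np.random.default_rng(0))
        assert np.array_equal(li.masks, before)

    def test_composition_matches_manual_pipeline(self):
        li = generate_cell_image(5, 16, (64, 64), seed=3)
        spec = DegradationSpec(
            mode="upsample", apply_blur=True, blur_sigma_y=1.5, blur_sigma_x=1.5,
            apply_downsample=True, ds_factor=2, pre_blur_sigma=0.8,
            apply_noise=True, poisson_scale=10.0,
        )
        out = apply_degradation(li, spec, np.random.default_rng(11))
        x = normalize_percentile(li.image)
        x = gaussian_blur(x, 1.5, 1.5)
        x = downsample_upsample(x, 2, pre_blur_sigma=0.8)
        x = add_poisson_noise(np.maximum(x, 0), 10.0, np.random.default_rng(11))
        assert np.array_equal(out, normalize_percentile(x))

    def test_axial_downsampling_degrades_y_only(self):
        li = generate_cell_image(5, 16, (64, 64), seed=4)
        spec = DegradationSpec(mode="aniso", apply_downsample=True, ds_factor=4,
                               ds_axial_only=True, pre_blur_sigma=0.0)
        out = apply_degradation(li, spec)
        x = normalize_percentile(li.image)
        manual = normalize_percentile(downsample_upsample(x, 4, pre_blur_sigma=0,
                                                          axial_only=True))
        assert np.array_equal(out, manual)
        assert decimate(x, 4, axial_only=True).shape == (16, 64)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DegradationSpec(mode="denoise", apply_downsample=True, ds_factor=1)
        with pytest.raises(ValueError):
            DegradationSpec(mode="denoise", apply_noise=True, poisson_scale=0.0)
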