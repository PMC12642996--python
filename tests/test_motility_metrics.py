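import numpy as np
import pytest

from doctkit import (
    PhantomSpec,
    PowerLaw,
    Region,
    SpectrumKind,
    TimeSeriesStack,
    ValidationError,
    WhiteNoise,
    compute_spectrum,
    fit_inverse_power_law,
    generate_phantom,
    layered_masks,
    motility_amplitude,
    motility_preset,
    shaped_noise_stack,
    smooth_spectra,
    temporal_stats,
)
from doctkit.motility_metrics import WeightRule

from conftest import pixel_stack


class TestMotilityAmplitude:
    def test_constant_pixel_zero(self):
        m = motility_amplitude(temporal_stats(pixel_stack([3.0] * 6)))
        assert m.values[0, 0] == 0.0

    def test_hand_value_1133(self):
        m = motility_amplitude(temporal_stats(pixel_stack([1.0, 1.0, 3.0, 3.0])))
        assert m.values[0, 0] == pytest.approx(np.sqrt(13.0 / 3.0 - 4.0) / 2.0)

    def test_anticorrelated_pixel_clamped(self):
        # Gamma = 0 < mean^2 = 1: negative radicand clamps to 0
        m = motility_amplitude(temporal_stats(pixel_stack([2.0, 0.0, 2.0, 0.0])))
        assert m.values[0, 0] == 0.0

    def test_exact_scale_invariance(self, random_stack):
        c = 9.0
        base = motility_amplitude(temporal_stats(random_stack)).values
        scaled = TimeSeriesStack(c * random_stack.frames, random_stack.frame_rate_hz)
        assert np.allclose(motility_amplitude(temporal_stats(scaled)).values, base, rtol=1e-12)

    def test_zero_mean_pixel_flagged(self):
        m = motility_amplitude(temporal_stats(pixel_stack([0.0, 0.0, 0.0])))
        assert np.isnan(m.values[0, 0])

    def test_near_snr_independence(self, rng):
        # M changes little between SNR 3 and SNR 10 for the same dynamics
        spec = PhantomSpec(
            (256, 24, 24), 100.0,
            [Region(np.ones((24, 24), bool), PowerLaw(1.0, 1.2))],
            detector_noise_level=0.0, seed=9,
        )
        stack, _ = generate_phantom(spec)
        meds = []
        for noise_level in (1.0 / 3.0, 0.1):  # SNR 3 and SNR 10
            noisy = stack.frames + rng.exponential(noise_level, stack.frames.shape)
            m = motility_amplitude(temporal_stats(TimeSeriesStack(noisy, 100.0)))
            meds.append(np.nanmedian(m.values))
        # white noise leaves the lag-1 numerator alone; only the mean shift
        # remains, so M(SNR) ~ 1/(1 + 1/SNR) -- mild compared to std-based metrics
        expected_ratio = (1 + 0.1) / (1 + 1 / 3)
        assert meds[0] / meds[1] == pytest.approx(expected_ratio, abs=0.05)


class TestSmoothSpectra:
    def test_constant_cube_is_fixed_point(self):
        cube = compute_spectrum(
            TimeSeriesStack(np.ones((8, 5, 5)) * 2.0, 10.0), SpectrumKind.POWER
        )
        smoothed = smooth_spectra(cube)
        assert np.allclose(smoothed.spectra, cube.spectra)

    def test_single_bright_pixel_spreads_ninth(self):
        frames = np.zeros((4, 7, 7))
        frames[:, 3, 3] = [1.0, 2.0, 1.0, 2.0]
        cube = compute_spectrum(TimeSeriesStack(frames, 8.0), SpectrumKind.POWER)
        smoothed = smooth_spectra(cube)
        for k in range(cube.freqs.size):
            center = cube.spectra[k, 3, 3]
            assert smoothed.spectra[k, 2:5, 2:5] == pytest.approx(center / 9.0)

    def test_matches_nine_term_oracle(self, rng):
        frames = rng.uniform(0.1, 1.0, (8, 6, 6))
        cube = compute_spectrum(TimeSeriesStack(frames, 8.0), SpectrumKind.POWER)
        smoothed = smooth_spectra(cube)
        padded = np.pad(cube.spectra, ((0, 0), (1, 1), (1, 1)), mode="symmetric")
        for i in range(6):
            for j in range(6):
                oracle = padded[:, i : i + 3, j : j + 3].mean(axis=(1, 2))
                assert np.allclose(smoothed.spectra[:, i, j], oracle, rtol=1e-12)

    def test_mean_conservation_interior(self, rng):
        frames = rng.uniform(0.1, 1.0, (8, 20, 20))
        cube = compute_spectrum(TimeSeriesStack(frames, 8.0), SpectrumKind.POWER)
        smoothed = smooth_spectra(cube)
        # reflect padding conserves each plane's mean up to edge effects
        assert np.allclose(
            smoothed.spectra.mean(axis=(1, 2)), cube.spectra.mean(axis=(1, 2)), rtol=0.02
        )

    def test_tiny_image_rejected(self):
        cube = compute_spectrum(TimeSeriesStack(np.ones((4, 2, 2)), 8.0), SpectrumKind.POWER)
        with pytest.raises(ValidationError):
            smooth_spectra(cube)

    def test_center_excluded_mode(self):
        frames = np.zeros((4, 5, 5))
        frames[:, 2, 2] = [1.0, 2.0, 1.0, 2.0]
        cube = compute_spectrum(TimeSeriesStack(frames, 8.0), SpectrumKind.POWER)
        smoothed = smooth_spectra(cube, include_center=False)
        # the bright pixel's own value is excluded from its neighborhood mean
        assert np.allclose(smoothed.spectra[:, 2, 2], 0.0, atol=1e-12)


class TestPowerLawFit:
    def test_exact_recovery(self):
        f = np.arange(1, 65, dtype=float)
        fit = fit_inverse_power_law(1.0 * f**-2.0 + 0.1, f)
        assert fit.converged
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.c0 == pytest.approx(1.0, abs=1e-6)
        assert fit.b0 == pytest.approx(0.1, abs=1e-6)

    def test_flat_spectrum_noise_dominated(self, rng):
        f = np.arange(1, 129, dtype=float)
        P = np.full(128, 3.0) + rng.normal(0, 0.05, 128)
        fit = fit_inverse_power_law(P, f)
        assert fit.alpha < 0.1 or fit.c0 * 1.0 ** (-fit.alpha) < 0.01 * P.mean()
        assert fit.b0 == pytest.approx(3.0, rel=0.1)
        assert fit.r_squared < 0.5

    def test_shaped_noise_recovery(self):
        # periodogram-level: median alpha within +-0.2 after 3x3 averaging
        alphas = []
        for rep in range(30):
            st = shaped_noise_stack(1.5, 512, (3, 3), 100.0, b0=0.01, seed=rep)
            cube = smooth_spectra(compute_spectrum(st, "power", "mean")).drop_dc()
            alphas.append(fit_inverse_power_law(cube.spectra[:, 1, 1], cube.freqs).alpha)
        assert abs(np.median(alphas) - 1.5) < 0.2

    def test_weight_rules_all_converge(self, rng):
        f = np.arange(1, 65, dtype=float)
        P = (2.0 * f**-1.0 + 0.2) * rng.gamma(9, 1 / 9, 64)
        for rule in WeightRule:
            fit = fit_inverse_power_law(P, f, rule)
            assert fit.converged
            assert 0.3 < fit.alpha < 1.7  # all rules land near the true exponent 1

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            fit_inverse_power_law(np.ones(4), np.arange(1.0, 5.0))
        with pytest.raises(ValidationError):
            fit_inverse_power_law(np.ones(6), np.arange(0.0, 6.0))  # f=0 forbidden


class TestMotilityPreset:
    def test_power_law_vs_noise_discrimination(self):
        masks = layered_masks(18, 18, 2)
        spec = PhantomSpec(
            (256, 18, 18), 100.0,
            [
                Region(masks[0], PowerLaw(1.0, 1.2), label=1),
                Region(masks[1], WhiteNoise(1.0), label=0),
            ],
            detector_noise_level=0.001, seed=17,
        )
        stack, labels = generate_phantom(spec)
        maps, img = motility_preset(stack)
        r2 = maps["R2"].values
        interior = np.zeros_like(labels, bool)
        interior[2:-2] = True  # keep away from the region boundary blur
        pl = (labels == 1) & interior
        wn = (labels == 0) & interior
        assert np.mean(r2[pl] > r2[wn].mean()) > 0.9
        assert np.nanmedian(maps["ALPHA"].values[pl]) > np.nanmedian(maps["ALPHA"].values[wn])

    def test_static_region_renders_black(self, rng):
        frames = np.broadcast_to(rng.uniform(0.5, 1.5, (1, 8, 8)), (64, 8, 8)).copy()
        stack = TimeSeriesStack(frames, 50.0)
        maps, img = motility_preset(stack)
        assert np.all(maps["M"].values == 0.0)
        assert img.rgb.max() <= 1e-9  # M -> brightness 0 -> black
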