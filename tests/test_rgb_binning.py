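import numpy as np
import pytest

from doctkit import (
    BinningMode,
    MetricMap,
    MetricName,
    NeuralGasConfig,
    SpectrumKind,
    TimeSeriesStack,
    ValidationError,
    bin_spectrum,
    compute_spectrum,
    cutoffs_from_units,
    enhance_channels,
    histogram_match,
    neural_gas_1d,
)

from conftest import pixel_stack


def lloyd_2means(samples, n_iter=100):
    """Independent 2-means oracle (Lloyd iterations) on 1D samples."""
    centers = np.percentile(samples, [25, 75]).astype(float)
    for _ in range(n_iter):
        assign = np.abs(samples[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([samples[assign == k].mean() for k in (0, 1)])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


class TestNeuralGas:
    def test_bimodal_units_near_modes(self):
        freqs = np.linspace(0.2, 50, 250)
        w = np.exp(-0.5 * ((freqs - 5) / 0.8) ** 2) + np.exp(-0.5 * ((freqs - 30) / 0.8) ** 2)
        binw = freqs[1] - freqs[0]
        for seed in range(10):
            units = neural_gas_1d(w, freqs, NeuralGasConfig(seed=seed, n_samples=2000))
            assert abs(units[0] - 5.0) < binw + 0.8
            assert abs(units[1] - 30.0) < binw + 0.8

    def test_degenerate_all_mass_one_bin(self):
        freqs = np.linspace(1, 10, 10)
        w = np.zeros(10)
        w[4] = 1.0
        units = neural_gas_1d(w, freqs, NeuralGasConfig(seed=1))
        assert np.all(units == freqs[4])  # both units converge to the single mode
        w[5] = 0.5  # two-bin support suffices for two units, not three
        with pytest.raises(ValidationError, match="cannot place"):
            neural_gas_1d(w, freqs, NeuralGasConfig(n_units=3))

    def test_uniform_mass_near_quartiles(self):
        freqs = np.linspace(0.5, 50, 100)
        w = np.ones(100)
        units = neural_gas_1d(w, freqs, NeuralGasConfig(seed=0, n_samples=4000))
        oracle = lloyd_2means(np.repeat(freqs, 50))
        # 2-quantizer of a uniform density sits near the 25 %/75 % points
        assert np.allclose(units, oracle, atol=2.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            neural_gas_1d(np.zeros(5), np.arange(5.0), NeuralGasConfig())


class TestCutoffs:
    def test_midpoint_two_units(self):
        freqs = np.arange(0.0, 50.0, 0.5)
        cut = cutoffs_from_units(np.array([5.0, 30.0]), freqs)
        assert cut.size == 1
        assert abs(cut[0] - 17.5) <= 0.25  # snapped to nearest bin edge

    def test_midpoints_three_units(self):
        freqs = np.arange(0.0, 51.0, 1.0)
        cut = cutoffs_from_units(np.array([2.0, 10.0, 40.0]), freqs)
        assert np.allclose(cut, [6.0, 25.0], atol=0.5)

    def test_snapping_to_grid(self):
        freqs = np.arange(0, 150) * 0.72  # trachea-regime grid
        cut = cutoffs_from_units(np.array([5.0, 30.0]), freqs)
        edges = 0.5 * (freqs[:-1] + freqs[1:])
        assert cut[0] in edges
        assert abs(cut[0] - 17.5) <= 0.36

    def test_coincident_units_flagged(self):
        with pytest.warns(UserWarning, match="coincident"):
            cutoffs_from_units(np.array([5.0, 5.0]), np.arange(0.0, 10.0))


class TestBinSpectrum:
    def test_constant_pixel_all_blue(self):
        cube = compute_spectrum(pixel_stack([4.0] * 16, rate=16.0), SpectrumKind.AMPLITUDE)
        blue, green, red = bin_spectrum(cube, [3.0])
        assert blue.values[0, 0] > 0
        assert green.values[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert red.values[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_nyquist_alternation_goes_red(self):
        series = np.tile([3.0, 1.0], 8)  # tone exactly at Nyquist + DC offset
        cube = compute_spectrum(pixel_stack(series, rate=16.0), SpectrumKind.AMPLITUDE)
        blue, green, red = bin_spectrum(cube, [4.0])
        assert red.values[0, 0] > 0
        assert green.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert blue.values[0, 0] > 0  # DC from the offset

    def test_channel_conservation(self, random_stack):
        cube = compute_spectrum(random_stack, SpectrumKind.AMPLITUDE)
        blue, green, red = bin_spectrum(cube, [10.0])
        total = cube.spectra.sum(axis=0)
        recombined = blue.values + green.values + red.values
        assert np.allclose(recombined, total, rtol=1e-9)

    def test_ffoct_mode_discards_dc_and_first_bin(self, random_stack):
        cube = compute_spectrum(random_stack, SpectrumKind.AMPLITUDE)
        blue, green, red = bin_spectrum(cube, [8.0, 16.0], BinningMode.FFOCT)
        recombined = blue.values + green.values + red.values
        total_wo = cube.spectra[2:].sum(axis=0)
        assert np.allclose(recombined, total_wo, rtol=1e-9)

    def test_cutoff_bounds_checked(self, random_stack):
        cube = compute_spectrum(random_stack, SpectrumKind.AMPLITUDE)
        with pytest.raises(ValidationError):
            bin_spectrum(cube, [30.0])  # past Nyquist of 25 Hz
        with pytest.raises(ValidationError, match="exactly one"):
            bin_spectrum(cube, [5.0, 10.0], BinningMode.STANDARD)


class TestEnhancement:
    def test_self_matching_near_identity(self, rng):
        values = rng.normal(0, 1, (100, 100))
        matched = histogram_match(values, values.copy())
        ranks = np.argsort(values.ravel())
        assert np.all(np.diff(matched.ravel()[ranks]) >= -1e-12)  # rank preserving
        # quantization error bounded by ~1/256 of the value range
        rescaled = (values - values.min()) / np.ptp(values)
        assert np.percentile(np.abs(matched - rescaled), 99) < 2.5 / 256

    def test_outlier_clipped_before_rescale(self):
        values = np.concatenate([np.linspace(0, 1, 99999), [1e6]]).reshape(200, 500)
        from doctkit.rgb_binning import _clip_rescale

        out = _clip_rescale(values, 0.1, 99.99)
        # the outlier saturates at 1, and the bulk keeps its spread
        assert out.max() == 1.0
        assert np.percentile(out, 99) < 1.0
        assert np.sum(out == 1.0) <= 12  # only the top 0.01 % tail saturates

    def test_ks_distance_to_target(self, rng):
        from scipy.stats import ks_2samp

        channel = rng.gamma(2.0, 1.0, (400, 250))
        target = rng.normal(5.0, 2.0, (400, 250))
        matched = histogram_match(channel, target)
        tgt = (target - target.min()) / np.ptp(target)
        stat = ks_2samp(matched.ravel(), tgt.ravel()).statistic
        assert stat < 0.02

    def test_matches_skimage_oracle(self, rng):
        from skimage.exposure import match_histograms

        channel = rng.gamma(2.0, 1.0, (120, 80))
        target = rng.normal(5.0, 2.0, (120, 80))
        ours = histogram_match(channel, target)
        oracle = match_histograms(channel, target)
        oracle = (oracle - oracle.min()) / np.ptp(oracle)
        assert np.percentile(np.abs(ours - oracle), 95) < 0.02

    def test_output_in_unit_interval_and_monotone(self, rng):
        maps = [
            MetricMap(rng.gamma(2, 1, (50, 50)), name)
            for name in (MetricName.BIN_BLUE, MetricName.BIN_GREEN, MetricName.BIN_RED)
        ]
        target = MetricMap(rng.normal(0, 1, (50, 50)), MetricName.LOG_STD)
        img = enhance_channels((maps[0], maps[1], maps[2]), target)
        assert img.rgb.min() >= 0 and img.rgb.max() <= 1
        # monotone (rank-preserving up to clipping ties): blue channel is rgb[..., 2]
        src = maps[0].values.ravel()
        out = img.rgb[..., 2].ravel()
        order = np.argsort(src)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_constant_channel_passthrough(self, rng):
        const = MetricMap(np.full((20, 20), 3.0), MetricName.BIN_RED)
        var = MetricMap(rng.gamma(2, 1, (20, 20)), MetricName.BIN_GREEN)
        target = MetricMap(rng.normal(0, 1, (20, 20)), MetricName.LOG_STD)
        with pytest.warns(UserWarning, match="constant channel"):
            img = enhance_channels((const, var, var), target)
        assert np.all(img.rgb[..., 2] == 0.0)
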