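"""Metric definitions: binning, periodogram moments, running std, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dffoct import (
    MetricConfig,
    bin_series,
    compute_dynamic_image,
    periodogram_psd,
    psd_frequency_std,
    psd_mean_frequency,
    render_hsb,
    running_std_mean,
)
from dffoct.dynamics import (
    BinTruncationWarning,
    ConfigurationError,
    DataError,
    NormalizationError,
)
from dffoct.signal_model import InterferometricStack


class TestBinSeries:
    def test_2560_at_500hz_bins_to_512_at_100hz(self):
        out = bin_series(np.arange(2560.0), 5)
        assert out.shape == (512,)

    def test_constant_series_unchanged(self):
        out = bin_series(np.full(100, 7.5), 5)
        assert np.all(out == 7.5)

    def test_truncation_warns(self):
        with pytest.warns(BinTruncationWarning):
            out = bin_series(np.arange(13.0), 5)
        assert out.shape == (2,)

    def test_invalid_width_rejected(self):
        with pytest.raises(ConfigurationError):
            bin_series(np.arange(10.0), 0)

    def test_noise_variance_reduced_by_bin_width(self):
        rng = np.random.default_rng(0)
        sigma = 2.0
        binned = rng.normal(0, sigma, (150_000, 5)).mean(axis=1)
        assert binned.var() == pytest.approx(sigma**2 / 5, rel=0.02)

    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_binning_conserves_the_mean(self, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 40 * k)
        assert bin_series(x, k).mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_snr_gain_is_sqrt_k(self):
        """Per-series mean/std improves by sqrt(5) after binning by 5."""
        rng = np.random.default_rng(7)
        mu, sigma, k = 20.0, 1.0, 5
        series = rng.normal(mu, sigma, (10_000, 2560))
        snr_before = series.mean(axis=1) / series.std(axis=1, ddof=1)
        binned = series.reshape(10_000, 512, k).mean(axis=2)
        snr_after = binned.mean(axis=1) / binned.std(axis=1, ddof=1)
        gain = snr_after.mean() / snr_before.mean()
        assert gain == pytest.approx(math.sqrt(5), rel=0.02)


class TestPeriodogram:
    def test_constant_series_has_zero_power(self):
        _, power = periodogram_psd(np.full(64, 3.0), 100.0)
        assert np.all(power == 0.0)

    def test_tone_at_exact_bin_concentrates_power(self):
        fs, n = 100.0, 100
        t = np.arange(n) / fs
        freqs, power = periodogram_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        assert freqs[np.argmax(power)] == pytest.approx(10.0)
        assert power[np.argmax(power)] / power.sum() > 1 - 1e-9

    def test_parseval_total_power_is_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.7, 512)
        freqs, power = periodogram_psd(x, 100.0)
        df = freqs[1] - freqs[0]
        assert power.sum() * df == pytest.approx(x.var(), rel=1e-9)

    def test_non_finite_input_rejected(self):
        x = np.ones(32)
        x[5] = np.nan
        with pytest.raises(DataError):
            periodogram_psd(x, 100.0)


class TestPsdMoments:
    def test_single_tone_mean_within_one_bin(self):
        fs, n = 100.0, 512
        t = np.arange(n) / fs
        freqs, power = periodogram_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        assert abs(psd_mean_frequency(freqs, power) - 10.0) <= fs / n

    def test_exact_bin_tone_has_zero_spread(self):
        fs, n = 100.0, 512
        tone = 51 * fs / n  # exactly on a frequency bin: no leakage
        t = np.arange(n) / fs
        freqs, power = periodogram_psd(np.sin(2 * np.pi * tone * t), fs)
        assert psd_mean_frequency(freqs, power) == pytest.approx(tone, abs=fs / n)
        assert psd_frequency_std(freqs, power) <= fs / n

    def test_two_equal_tones_brute_force_moments(self):
        # exact-bin tones at 5 and 15 Hz: two-point distribution with
        # mean 10 and standard deviation 5
        fs, n = 100.0, 100
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        freqs, power = periodogram_psd(x, fs)
        assert psd_mean_frequency(freqs, power) == pytest.approx(10.0, abs=1e-9)
        assert psd_frequency_std(freqs, power) == pytest.approx(5.0, abs=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        freqs = np.array([0.0, 1.0, 2.0, 3.0])
        power = np.array([0.5, 1.0, 2.0, 1.5])
        base = psd_mean_frequency(freqs, power)
        assert psd_mean_frequency(freqs, power * scale) == pytest.approx(base)

    def test_all_zero_power_is_flagged_no_signal(self):
        freqs = np.array([0.0, 1.0, 2.0])
        power = np.array([5.0, 0.0, 0.0])  # only DC
        assert np.isnan(psd_mean_frequency(freqs, power))
        assert np.isnan(psd_frequency_std(freqs, power))


class TestRunningStd:
    def test_constant_series_gives_zero(self):
        # 4.5 is exactly representable, so every window std is exactly zero
        assert running_std_mean(np.full(100, 4.5), 50) == 0.0
        assert running_std_mean(np.full(100, 4.2), 50) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        assert running_std_mean(x + 123.4, 50) == pytest.approx(
            running_std_mean(x, 50), rel=1e-12
        )

    def test_window_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            running_std_mean(np.arange(10.0), 1)
        with pytest.raises(DataError):
            running_std_mean(np.arange(10.0), 11)

    def test_gaussian_expectation_matches_c4_bias_factor(self):
        """E[sample std] = sigma * c4(n) for Gaussian data."""
        w, sigma = 50, 3.0
        c4 = math.sqrt(2 / (w - 1)) * math.gamma(w / 2) / math.gamma((w - 1) / 2)
        rng = np.random.default_rng(11)
        stds = rng.normal(0, sigma, (10_000, w)).std(axis=1, ddof=1)
        se = stds.std(ddof=1) / math.sqrt(len(stds))
        assert abs(stds.mean() - sigma * c4) < 2 * se


class TestComputeDynamicImage:
    def test_matches_per_pixel_scalar_loop_bit_for_bit(self, two_regime_stack):
        crop = InterferometricStack(
            intensities=two_regime_stack.intensities[:, :16, 8:24],
            frame_rate_hz=two_regime_stack.frame_rate_hz,
        )
        cfg = MetricConfig()
        metrics = compute_dynamic_image(crop, cfg)
        for r in range(16):
            for c in range(16):
                series = crop.intensities[: cfg.n_frames, r, c]
                freqs, power = periodogram_psd(series, cfg.fs_hz)
                assert psd_mean_frequency(freqs, power) == metrics.mean_frequency_hz[r, c]
                assert psd_frequency_std(freqs, power) == metrics.frequency_std_hz[r, c]
                assert running_std_mean(series, cfg.running_window) == metrics.amplitude[r, c]

    def test_binned_path_matches_scalar_loop(self, rpc_band_stack):
        from dffoct import PixelDynamicsParams, simulate_phantom_stack

        mask = np.ones((4, 4), dtype=bool)
        params = PixelDynamicsParams(regime_label="r", target_mean_freq_hz=6.0)
        stack = simulate_phantom_stack(
            [(mask, params)], (4, 4), 2560, 500.0, seed=13
        )
        cfg = MetricConfig(bin_width=5)
        metrics = compute_dynamic_image(stack, cfg)
        for r in range(4):
            for c in range(4):
                series = bin_series(stack.intensities[:, r, c], 5)[: cfg.n_frames]
                freqs, power = periodogram_psd(series, cfg.fs_hz)
                assert psd_mean_frequency(freqs, power) == metrics.mean_frequency_hz[r, c]
                assert running_std_mean(series, cfg.running_window) == metrics.amplitude[r, c]

    def test_metric_bounds(self, two_regime_metrics):
        m = two_regime_metrics
        nyquist = m.config.fs_hz / 2
        finite = np.isfinite(m.mean_frequency_hz)
        assert np.all(m.mean_frequency_hz[finite] > 0)
        assert np.all(m.mean_frequency_hz[finite] <= nyquist)
        assert np.all(m.frequency_std_hz[np.isfinite(m.frequency_std_hz)] >= 0)
        assert np.all(m.amplitude >= 0)

    def test_regime_ordering_and_separation(self, two_regime_metrics, two_regime_stack):
        mf = two_regime_metrics.mean_frequency_hz
        slow = mf[two_regime_stack.truth_labels == 1]
        fast = mf[two_regime_stack.truth_labels == 2]
        assert np.median(slow) < np.median(fast)
        # interquartile ranges must not overlap
        assert np.percentile(slow, 75) < np.percentile(fast, 25)

    def test_incompatible_rate_rejected(self, two_regime_stack):
        cfg = MetricConfig(fs_hz=80.0, hue_max_hz=13.0)
        with pytest.raises(ConfigurationError):
            compute_dynamic_image(two_regime_stack, cfg)

    def test_band_recovery_for_rpc_like_regime(self, rpc_band_stack):
        """>= 90% of pixels of a 5.5-8 Hz regime are recovered in band."""
        metrics = compute_dynamic_image(rpc_band_stack, MetricConfig())
        mf = metrics.mean_frequency_hz
        in_band = (mf >= 5.5) & (mf <= 8.0)
        assert in_band.mean() >= 0.90


class TestRenderHsb:
    @staticmethod
    def _metrics(mean_freq, spread=0.0, amp=None):
        mf = np.asarray(mean_freq, dtype=np.float64)
        from dffoct import DynamicMetrics

        return DynamicMetrics(
            mean_frequency_hz=mf,
            frequency_std_hz=np.full_like(mf, spread),
            amplitude=np.ones_like(mf) if amp is None else np.asarray(amp, float),
            config=MetricConfig(),
        )

    def test_hue_clamps_at_band_edges(self):
        metrics = self._metrics([[2.0, 3.0, 13.0, 20.0]])
        render = render_hsb(metrics)
        blue, red = 240.0 / 360.0, 0.0
        assert render.hue[0, 0] == blue
        assert render.hue[0, 1] == blue
        assert render.hue[0, 2] == red
        assert render.hue[0, 3] == red

    def test_hue_midpoint_at_8hz(self):
        render = render_hsb(self._metrics([[8.0]]))
        assert render.hue[0, 0] == pytest.approx(0.5 * 240.0 / 360.0)

    def test_zero_amplitude_renders_black(self):
        metrics = self._metrics([[5.0, 9.0]], amp=[[0.0, 0.0]])
        render = render_hsb(metrics)
        assert np.all(render.rgb == 0.0)

    def test_no_signal_pixels_are_black(self):
        metrics = self._metrics([[np.nan, 8.0]], amp=[[5.0, 5.0]])
        render = render_hsb(metrics)
        assert np.all(render.rgb[0, 0] == 0.0)

    def test_saturation_decreases_with_spread(self):
        narrow = render_hsb(self._metrics([[8.0]], spread=1.0))
        broad = render_hsb(self._metrics([[8.0]], spread=10.0))
        assert broad.saturation[0, 0] < narrow.saturation[0, 0]

    def test_degenerate_percentiles_rejected(self):
        with pytest.raises(NormalizationError):
            MetricConfig(brightness_percentiles=(50.0, 50.0))
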