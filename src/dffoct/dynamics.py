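"""Per-pixel dynamic-contrast metrics and HSB rendering.

Three metrics are computed from each pixel's intensity time series:

* **mean frequency** -- power-weighted average of the periodogram frequency
  (DC excluded),
* **frequency spread** -- power-weighted standard deviation of the
  periodogram frequency,
* **amplitude** -- mean of the running standard deviation in a sliding
  temporal window (default 50 samples).

They are rendered as a hue-saturation-brightness composite: hue maps mean
frequency linearly over a display band (default 3-13 Hz, blue -> red),
saturation decreases with the frequency spread (narrowband activity is
vivid), and brightness is the percentile-normalised amplitude.

Series acquired at a higher rate (e.g. 2560 frames at 500 Hz) are first
averaged in groups of ``bin_width`` consecutive frames (temporal binning),
which trades rate for a sqrt(bin_width) SNR gain on white noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = [
    "MetricConfig",
    "DynamicMetrics",
    "HSBRender",
    "DataError",
    "ConfigurationError",
    "NormalizationError",
    "BinTruncationWarning",
    "NO_SIGNAL",
    "bin_series",
    "periodogram_psd",
    "psd_mean_frequency",
    "psd_frequency_std",
    "running_std_mean",
    "compute_dynamic_image",
    "render_hsb",
]

#: Flag value for pixels with no spectral power above DC (rendered black).
NO_SIGNAL = np.nan


class DataError(ValueError):
    """Raised for non-finite or otherwise unusable input data."""


class ConfigurationError(ValueError):
    """Raised when a stack cannot be brought to the configured rate/length."""


class NormalizationError(ValueError):
    """Raised for a degenerate brightness percentile configuration."""


class BinTruncationWarning(UserWarning):
    """Emitted when temporal binning discards a trailing remainder."""


@dataclass(frozen=True)
class MetricConfig:
    """Processing parameters for one acquisition.

    Defaults follow the standard operating point: 512 frames at 100 Hz,
    sliding window of 50 samples, hue display band 3-13 Hz.  ``bin_width=5``
    is used for 500 Hz acquisitions that are recast to an effective 100 Hz.
    """

    n_frames: int = 512
    fs_hz: float = 100.0
    bin_width: int = 1
    running_window: int = 50
    hue_min_hz: float = 3.0
    hue_max_hz: float = 13.0
    brightness_percentiles: tuple[float, float] = (1.0, 99.9)
    saturation_scale: str = "quarter-nyquist"

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ConfigurationError("bin_width must be >= 1")
        if not 2 <= self.running_window < self.n_frames:
            raise ConfigurationError(
                "running_window must satisfy 2 <= window < n_frames"
            )
        if not 0 < self.hue_min_hz < self.hue_max_hz <= self.fs_hz / 2:
            raise ConfigurationError(
                "need 0 < hue_min_hz < hue_max_hz <= fs/2"
            )
        lo, hi = self.brightness_percentiles
        if not (0 <= lo < hi <= 100):
            raise NormalizationError(
                "brightness_percentiles must be an increasing pair in [0,100]"
            )


@dataclass
class DynamicMetrics:
    """The three co-registered metric planes for one field of view."""

    mean_frequency_hz: np.ndarray
    frequency_std_hz: np.ndarray
    amplitude: np.ndarray
    config: MetricConfig

    def __post_init__(self) -> None:
        shapes = {
            self.mean_frequency_hz.shape,
            self.frequency_std_hz.shape,
            self.amplitude.shape,
        }
        if len(shapes) != 1:
            raise DataError("metric planes must share one shape")
        nyquist = self.config.fs_hz / 2
        mf = self.mean_frequency_hz
        finite = np.isfinite(mf)
        if np.any((mf[finite] < 0) | (mf[finite] > nyquist + 1e-9)):
            raise DataError("mean frequency out of (0, fs/2]")
        fs = self.frequency_std_hz
        if np.any(fs[np.isfinite(fs)] < 0):
            raise DataError("frequency spread must be >= 0")
        if np.any(self.amplitude < 0):
            raise DataError("amplitude must be >= 0")


@dataclass
class HSBRender:
    """RGB render plus the HSB channels and normalisation actually applied."""

    rgb: np.ndarray
    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray
    brightness_bounds: tuple[float, float]


# --------------------------------------------------------------------------
# Scalar building blocks (shared verbatim by the vectorized image path)


def _bin_last_axis(x: np.ndarray, k: int) -> np.ndarray:
    n_out = x.shape[-1] // k
    return x[..., : n_out * k].reshape(*x.shape[:-1], n_out, k).mean(axis=-1)


def bin_series(series: np.ndarray, k: int, axis: int = 0) -> np.ndarray:
    """Average groups of ``k`` consecutive samples along ``axis``.

    The output has ``floor(n / k)`` samples at an effective rate ``fs / k``;
    a non-divisible tail is truncated with a :class:`BinTruncationWarning`.
    """
    if k < 1:
        raise ConfigurationError("bin width k must be >= 1")
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[axis]
    if n % k:
        warnings.warn(
            f"binning discards {n % k} trailing sample(s) "
            f"(length {n} not divisible by {k})",
            BinTruncationWarning,
            stacklevel=2,
        )
    moved = np.moveaxis(series, axis, -1)
    return np.moveaxis(_bin_last_axis(moved, k), -1, axis)


def _periodogram_last_axis(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[-1]
    centered = x - x.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(centered, axis=-1)
    power = (spectrum.real**2 + spectrum.imag**2) / (fs * n)
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, power


def periodogram_psd(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed series (rectangular window).

    Density scaling: ``sum(power) * fs / n`` equals the series' sample
    variance (Parseval).  The frequency grid spans 0..fs/2 with spacing fs/n.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise DataError("series must be 1-D with at least 2 samples")
    if fs <= 0:
        raise DataError("fs must be positive")
    if not np.all(np.isfinite(series)):
        raise DataError("series contains non-finite values")
    return _periodogram_last_axis(series, fs)


def _psd_moments_last_axis(
    freqs: np.ndarray, power: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Power-weighted frequency mean and spread, DC excluded (vectorized)."""
    w = power[..., 1:]
    f = freqs[1:]
    total = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (f * w).sum(axis=-1) / total
        var = ((f - mean[..., None]) ** 2 * w).sum(axis=-1) / total
        std = np.sqrt(var)
    no_signal = total <= 0.0
    mean = np.where(no_signal, NO_SIGNAL, mean)
    std = np.where(no_signal, NO_SIGNAL, std)
    return mean, std


def _check_psd_args(freqs: np.ndarray, power: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.asarray(freqs, dtype=np.float64)
    power = np.asarray(power, dtype=np.float64)
    if freqs.shape != power.shape or freqs.ndim != 1:
        raise DataError("frequency grid and power must be matching 1-D arrays")
    if np.any(power < 0):
        raise DataError("power values must be >= 0")
    return freqs, power


def psd_mean_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Power-weighted mean frequency, excluding the DC bin.

    Returns :data:`NO_SIGNAL` (NaN) when all non-DC power is zero; the value
    is invariant to any positive rescaling of ``power``.
    """
    freqs, power = _check_psd_args(freqs, power)
    mean, _ = _psd_moments_last_axis(freqs, power)
    return float(mean)


def psd_frequency_std(freqs: np.ndarray, power: np.ndarray) -> float:
    """Power-weighted standard deviation of frequency, excluding DC."""
    freqs, power = _check_psd_args(freqs, power)
    _, std = _psd_moments_last_axis(freqs, power)
    return float(std)


def _running_std_mean_last_axis(x: np.ndarray, window: int) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(x, window, axis=-1)
    return windows.std(axis=-1, ddof=1).mean(axis=-1)


def running_std_mean(series: np.ndarray, window: int) -> float:
    """Mean over all stride-1 windows of the in-window sample std (ddof=1).

    Windows lie fully inside the series (no padding); the result is invariant
    to adding a constant to the series.
    """
    series = np.asarray(series, dtype=np.float64)
    if window < 2:
        raise ConfigurationError("window must be >= 2")
    if series.ndim != 1 or series.size < window:
        raise DataError("series must be 1-D with length >= window")
    return float(_running_std_mean_last_axis(series, window))


# --------------------------------------------------------------------------
# Image-level operations


def compute_dynamic_image(stack, config: MetricConfig) -> DynamicMetrics:
    """Compute the three metric planes for every pixel of a stack.

    If the stack rate equals ``config.fs_hz * config.bin_width`` the stack is
    first binned in groups of ``bin_width`` frames; it must then provide at
    least ``config.n_frames`` frames, of which the first ``n_frames`` are
    used.  The vectorized computation applies exactly the scalar operations
    (same reductions over a contiguous time axis), so it matches an explicit
    per-pixel loop bit for bit.
    """
    data = np.asarray(stack.intensities, dtype=np.float64)
    fs_in = float(stack.frame_rate_hz)
    cfg = config
    if math.isclose(fs_in, cfg.fs_hz * cfg.bin_width) and cfg.bin_width > 1:
        k = cfg.bin_width
    elif math.isclose(fs_in, cfg.fs_hz):
        k = 1
    else:
        raise ConfigurationError(
            f"stack rate {fs_in} Hz incompatible with config "
            f"fs={cfg.fs_hz} Hz, bin_width={cfg.bin_width}"
        )
    if data.shape[0] // k < cfg.n_frames:
        raise ConfigurationError(
            f"stack provides {data.shape[0] // k} frames after binning; "
            f"{cfg.n_frames} required"
        )

    # Time-last contiguous layout so every reduction runs over the inner axis,
    # exactly as in the scalar functions.
    arr = np.ascontiguousarray(np.moveaxis(data, 0, -1))
    if k > 1:
        arr = _bin_last_axis(arr, k)
    arr = np.ascontiguousarray(arr[..., : cfg.n_frames])

    freqs, power = _periodogram_last_axis(arr, cfg.fs_hz)
    mean_freq, freq_std = _psd_moments_last_axis(freqs, power)
    amplitude = _running_std_mean_last_axis(arr, cfg.running_window)
    return DynamicMetrics(
        mean_frequency_hz=mean_freq,
        frequency_std_hz=freq_std,
        amplitude=amplitude,
        config=cfg,
    )


def render_hsb(metrics: DynamicMetrics, config: MetricConfig | None = None) -> HSBRender:
    """Render metric planes as an HSB/HSV composite.

    Hue maps mean frequency linearly from ``hue_min_hz`` (blue, 240 deg) to
    ``hue_max_hz`` (red, 0 deg), clamped at the band edges.  Saturation is
    ``1 - spread / (fs/4)`` clipped to [0, 1].  Brightness is the amplitude
    normalised between the configured global percentiles; if the amplitude
    plane is constant the render is black.  No-signal pixels are black.
    """
    cfg = config if config is not None else metrics.config
    lo_p, hi_p = cfg.brightness_percentiles
    if lo_p == hi_p:
        raise NormalizationError("brightness percentiles must differ")

    mf = metrics.mean_frequency_hz
    no_signal = ~np.isfinite(mf)
    t = (np.where(no_signal, cfg.hue_min_hz, mf) - cfg.hue_min_hz) / (
        cfg.hue_max_hz - cfg.hue_min_hz
    )
    t = np.clip(t, 0.0, 1.0)
    hue = (240.0 / 360.0) * (1.0 - t)  # blue at the low end, red at the high

    spread = np.where(no_signal, 0.0, metrics.frequency_std_hz)
    saturation = np.clip(1.0 - spread / (cfg.fs_hz / 4.0), 0.0, 1.0)

    amp = metrics.amplitude
    lo, hi = np.percentile(amp, [lo_p, hi_p])
    if hi > lo:
        brightness = np.clip((amp - lo) / (hi - lo), 0.0, 1.0)
    else:
        brightness = np.zeros_like(amp)
    brightness = np.where(no_signal, 0.0, brightness)

    rgb = hsv_to_rgb(np.stack([hue, saturation, brightness], axis=-1))
    return HSBRender(
        rgb=np.clip(rgb, 0.0, 1.0),
        hue=hue,
        saturation=saturation,
        brightness=brightness,
        brightness_bounds=(float(lo), float(hi)),
    )
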