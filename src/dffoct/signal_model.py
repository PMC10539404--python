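"""Synthetic interferometric phantoms with known ground truth.

Dynamic full-field OCT derives contrast from temporal fluctuations of the
interferometric intensity recorded at every camera pixel.  Real acquisitions
need an interferometer; this module emulates the *statistics* of the signal so
that the whole processing chain (spectral metrics, rendering, mosaicking,
counting) can be exercised and validated on a desktop.

The per-pixel generative model is::

    I(t) = baseline + A * cos(phi(t)) + n(t)

where ``phi`` is a Brownian (random-walk) phase whose increment variance is set
by a correlation time ``tau`` (autocorrelation of ``cos(phi)`` decays as
``exp(-|t|/tau)``, i.e. a Lorentzian line of half-width ``1/(2*pi*tau)``), and
``n`` is additive Gaussian camera noise.  The mapping between a *target* mean
PSD frequency and ``tau`` is calibrated numerically from the expected
finite-sample periodogram, so phantom regimes can be specified directly in
hertz (e.g. a retinal-progenitor-like band of 5.5-8 Hz).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FULL_SCALE_COUNTS",
    "CameraConfig",
    "OpticsConfig",
    "PixelDynamicsParams",
    "InterferometricStack",
    "StainedZStack",
    "TileSet",
    "SimulationParameterError",
    "LayoutError",
    "GeometryError",
    "PackingError",
    "expected_mean_frequency",
    "correlation_time_for_mean_frequency",
    "simulate_pixel_series",
    "simulate_phantom_stack",
    "simulate_tile_set",
    "simulate_stained_zstack",
    "quantize_counts",
]

#: Full scale of the 16-bit files written by :mod:`dffoct.io`.
FULL_SCALE_COUNTS = 65535


class SimulationParameterError(ValueError):
    """Raised for invalid generator parameters (non-positive sizes/rates)."""


class LayoutError(ValueError):
    """Raised when phantom regions overlap or do not fit the canvas."""


class GeometryError(ValueError):
    """Raised when a tile grid does not fit inside the source scene."""


class PackingError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails after retries."""


@dataclass(frozen=True)
class CameraConfig:
    """Camera operating point.

    Defaults correspond to a 1440 x 1440 CMOS sensor with 10 um pitch run near
    95% of its full-well capacity, giving a shot-noise-limited SNR of ~1071,
    at a 100 Hz frame rate.
    """

    frame_rate_hz: float = 100.0
    exposure_s: float = 3.9e-3
    sensor_pixels: tuple[int, int] = (1440, 1440)
    pixel_pitch_um: float = 10.0
    fwc_fraction: float = 0.95
    snr_level: float = 1071.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise SimulationParameterError("frame_rate_hz must be positive")
        if not 0.0 < self.exposure_s <= 1.0 / self.frame_rate_hz:
            raise SimulationParameterError(
                "exposure_s must lie in (0, 1/frame_rate_hz]"
            )
        if not 0.0 < self.fwc_fraction <= 1.0:
            raise SimulationParameterError("fwc_fraction must lie in (0, 1]")

    @property
    def baseline_counts(self) -> float:
        """Mean signal level in 16-bit counts at the configured FWC fraction."""
        return self.fwc_fraction * FULL_SCALE_COUNTS

    @property
    def noise_sd_counts(self) -> float:
        """Shot-noise standard deviation in counts implied by ``snr_level``."""
        return self.baseline_counts / self.snr_level


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging-path metadata (magnification, field, source)."""

    magnification: float = 58.0
    field_um: float = 200.0
    sensor_width_px: int = 1440
    wavelength_nm: float = 730.0
    power_mw: float = 3.3

    @property
    def sample_pixel_nm(self) -> float:
        """Object-space pixel size: field width divided by sensor pixels.

        200 um across 1440 pixels gives 139 nm per pixel.
        """
        return self.field_um * 1000.0 / self.sensor_width_px


@dataclass(frozen=True)
class PixelDynamicsParams:
    """Parameters of one dynamic regime.

    Exactly one of ``target_mean_freq_hz`` and ``phase_correlation_time_s``
    needs to be set for a fluctuating pixel (``fringe_amplitude > 0``); a
    target frequency is converted to a correlation time by numerical
    calibration against the expected periodogram.
    """

    regime_label: str = "regime"
    target_mean_freq_hz: float | None = None
    phase_correlation_time_s: float | None = None
    fringe_amplitude: float = 2000.0
    baseline_offset: float = 0.95 * FULL_SCALE_COUNTS
    noise_sd: float = 58.0
    #: The metric configuration a target mean frequency refers to.  A 500 Hz
    #: acquisition binned in groups of 5 is analysed as 512 frames at 100 Hz,
    #: so the same regime can be simulated at either rate.
    analysis_n_frames: int = 512
    analysis_fs_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.fringe_amplitude < 0 or self.noise_sd < 0:
            raise SimulationParameterError("amplitudes and noise must be >= 0")
        if self.baseline_offset < 0:
            raise SimulationParameterError("baseline_offset must be >= 0")
        if (
            self.target_mean_freq_hz is not None
            and self.target_mean_freq_hz < 0
        ):
            raise SimulationParameterError("target_mean_freq_hz must be >= 0")
        if (
            self.phase_correlation_time_s is not None
            and self.phase_correlation_time_s <= 0
        ):
            raise SimulationParameterError(
                "phase_correlation_time_s must be > 0"
            )

    def resolved_correlation_time(self) -> float:
        """Correlation time to simulate with, calibrating if needed.

        A target mean frequency is inverted against the expected periodogram
        of the *analysis* condition (``analysis_n_frames`` samples at
        ``analysis_fs_hz``), which is where the downstream metric is defined.
        """
        if self.phase_correlation_time_s is not None:
            return self.phase_correlation_time_s
        if self.target_mean_freq_hz is None:
            raise SimulationParameterError(
                "set target_mean_freq_hz or phase_correlation_time_s for a "
                "fluctuating regime"
            )
        return correlation_time_for_mean_frequency(
            self.target_mean_freq_hz,
            self.analysis_n_frames,
            self.analysis_fs_hz,
            fringe_amplitude=self.fringe_amplitude,
            noise_sd=self.noise_sd,
        )


def static_background(
    baseline_offset: float = 0.95 * FULL_SCALE_COUNTS, noise_sd: float = 58.0
) -> PixelDynamicsParams:
    """A non-fluctuating pixel regime: camera noise on a constant baseline."""
    return PixelDynamicsParams(
        regime_label="background",
        fringe_amplitude=0.0,
        baseline_offset=baseline_offset,
        noise_sd=noise_sd,
    )


@dataclass
class InterferometricStack:
    """A (frames x rows x cols) intensity cube plus acquisition metadata."""

    intensities: np.ndarray
    frame_rate_hz: float
    camera: CameraConfig | None = None
    optics: OpticsConfig | None = None
    truth_labels: np.ndarray | None = None
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise SimulationParameterError(
                "intensities must be (frames, rows, cols)"
            )
        if self.frame_rate_hz <= 0:
            raise SimulationParameterError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise SimulationParameterError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise SimulationParameterError("intensities must be >= 0")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if self.truth_labels.shape != self.intensities.shape[1:]:
                raise SimulationParameterError(
                    "truth_labels must match the spatial shape"
                )

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class TileSet:
    """Overlapping tiles cut from a scene, with their true pixel offsets."""

    tiles: list[np.ndarray]
    true_offsets: np.ndarray  # (n_tiles, 2) of (y, x) top-left corners
    grid_shape: tuple[int, int]
    tile_px: int
    step_px: int
    scene_shape: tuple[int, int]


@dataclass
class StainedZStack:
    """Synthetic fluorescence z-stack of disk-shaped nuclei."""

    stack: np.ndarray  # (planes, rows, cols)
    centers: np.ndarray  # (n_cells, 2) of (row, col)
    planes: np.ndarray  # (n_cells,) plane index of each nucleus
    cell_area_px: int
    fg_level: float
    bg_level: float


# --------------------------------------------------------------------------
# Spectral calibration


def expected_mean_frequency(
    tau_s: float,
    n_frames: int,
    fs_hz: float,
    fringe_amplitude: float = 1.0,
    noise_sd: float = 0.0,
) -> float:
    """Expected periodogram mean frequency of the phase-diffusion model.

    Computed from the exact autocovariance ``r(k) = A^2/2 * exp(-k/(fs*tau))``
    through the Bartlett-windowed (finite-sample) expected periodogram, with a
    flat floor of ``noise_sd**2`` for the additive camera noise.  The DC bin is
    excluded, matching the downstream metric definition.
    """
    if tau_s <= 0 or n_frames < 2 or fs_hz <= 0:
        raise SimulationParameterError("tau_s, n_frames, fs_hz must be positive")
    k = np.arange(n_frames)
    r = 0.5 * fringe_amplitude**2 * np.exp(-k / (fs_hz * tau_s))
    a = np.empty(n_frames)
    a[0] = r[0]
    a[1:] = 2.0 * (1.0 - k[1:] / n_frames) * r[1:]
    spectrum = np.clip(np.fft.rfft(a).real, 0.0, None) + noise_sd**2
    freqs = np.fft.rfftfreq(n_frames, 1.0 / fs_hz)
    weights = spectrum[1:]
    return float((freqs[1:] * weights).sum() / weights.sum())


@functools.lru_cache(maxsize=256)
def _calibrate_cached(
    target_hz: float,
    n_frames: int,
    fs_hz: float,
    fringe_amplitude: float,
    noise_sd: float,
) -> float:
    tau_lo, tau_hi = 1e-5, 100.0
    lo = expected_mean_frequency(tau_hi, n_frames, fs_hz, fringe_amplitude, noise_sd)
    hi = expected_mean_frequency(tau_lo, n_frames, fs_hz, fringe_amplitude, noise_sd)
    if not lo < target_hz < hi:
        raise SimulationParameterError(
            f"target mean frequency {target_hz} Hz outside the attainable "
            f"range ({lo:.3f}, {hi:.3f}) Hz for n={n_frames}, fs={fs_hz}"
        )

    def objective(log_tau: float) -> float:
        return (
            expected_mean_frequency(
                math.exp(log_tau), n_frames, fs_hz, fringe_amplitude, noise_sd
            )
            - target_hz
        )

    log_tau = brentq(objective, math.log(tau_lo), math.log(tau_hi), xtol=1e-12)
    return math.exp(log_tau)


def correlation_time_for_mean_frequency(
    target_hz: float,
    n_frames: int,
    fs_hz: float,
    fringe_amplitude: float = 1.0,
    noise_sd: float = 0.0,
) -> float:
    """Invert :func:`expected_mean_frequency` for the correlation time.

    The mapping is strictly monotone (shorter correlation time = wider
    Lorentzian = higher mean frequency), so a bracketed root search on
    ``log(tau)`` is exact to floating precision.  Results are cached.
    """
    if not 0 < target_hz < fs_hz / 2:
        raise SimulationParameterError(
            "target mean frequency must lie in (0, fs/2)"
        )
    return _calibrate_cached(
        float(target_hz), int(n_frames), float(fs_hz),
        float(fringe_amplitude), float(noise_sd),
    )


# --------------------------------------------------------------------------
# Generators


def _pixel_series(
    params: PixelDynamicsParams,
    n_frames: int,
    fs_hz: float,
    tau_s: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if params.fringe_amplitude > 0:
        increment_sd = math.sqrt(2.0 / (fs_hz * tau_s))
        phi0 = rng.uniform(0.0, 2.0 * math.pi)
        dphi = rng.normal(0.0, increment_sd, n_frames - 1)
        phase = phi0 + np.concatenate(([0.0], np.cumsum(dphi)))
        series = params.baseline_offset + params.fringe_amplitude * np.cos(phase)
    else:
        series = np.full(n_frames, params.baseline_offset)
    if params.noise_sd > 0:
        series = series + rng.normal(0.0, params.noise_sd, n_frames)
    return series


def simulate_pixel_series(
    params: PixelDynamicsParams,
    n_frames: int,
    fs_hz: float,
    seed: int,
) -> np.ndarray:
    """Simulate one pixel's intensity time series.

    Identical ``(params, n_frames, fs_hz, seed)`` give bit-identical output.
    The temporal expectation equals ``params.baseline_offset``.
    """
    if n_frames < 2:
        raise SimulationParameterError("n_frames must be >= 2")
    if fs_hz <= 0:
        raise SimulationParameterError("fs_hz must be positive")
    tau = (
        params.resolved_correlation_time()
        if params.fringe_amplitude > 0
        else None
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _pixel_series(params, n_frames, fs_hz, tau, rng)


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    # Child streams keyed on the pixel coordinate, so any spatial subset of a
    # phantom is reproducible independently of generation order.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(row, col))
    )


def simulate_phantom_stack(
    layout: Sequence[tuple[np.ndarray, PixelDynamicsParams]],
    shape: tuple[int, int],
    n_frames: int,
    fs_hz: float,
    seed: int,
    background: PixelDynamicsParams | None = None,
    camera: CameraConfig | None = None,
    optics: OpticsConfig | None = None,
) -> InterferometricStack:
    """Simulate a structured phantom stack with per-region dynamics.

    Parameters
    ----------
    layout
        Sequence of ``(mask, params)`` pairs; masks are boolean images of
        ``shape`` and must be pairwise disjoint.  Pixels covered by no mask
        follow ``background`` (static baseline + camera noise by default).
    shape
        Spatial shape ``(rows, cols)``.
    n_frames, fs_hz, seed
        Length, sampling rate, and root seed of the simulation.

    Returns
    -------
    InterferometricStack
        With ``truth_labels`` set to 0 for background and ``i + 1`` for the
        i-th layout region, and ``label_names`` mapping labels to regimes.
    """
    if n_frames < 2 or fs_hz <= 0:
        raise SimulationParameterError("n_frames >= 2 and fs_hz > 0 required")
    rows, cols = shape
    if background is None:
        background = static_background()

    coverage = np.zeros(shape, dtype=np.int64)
    labels = np.zeros(shape, dtype=np.int32)
    label_names = {0: background.regime_label}
    region_params: list[PixelDynamicsParams] = [background]
    region_tau: list[float | None] = [
        background.resolved_correlation_time()
        if background.fringe_amplitude > 0
        else None
    ]
    for i, (mask, params) in enumerate(layout):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise LayoutError("region mask shape must match the phantom shape")
        coverage += mask
        labels[mask] = i + 1
        label_names[i + 1] = params.regime_label
        region_params.append(params)
        region_tau.append(
            params.resolved_correlation_time()
            if params.fringe_amplitude > 0
            else None
        )
    if np.any(coverage > 1):
        raise LayoutError("phantom regions overlap")

    data = np.empty((n_frames, rows, cols))
    for r in range(rows):
        for c in range(cols):
            idx = labels[r, c]
            data[:, r, c] = _pixel_series(
                region_params[idx], n_frames, fs_hz, region_tau[idx],
                _pixel_rng(seed, r, c),
            )
    np.clip(data, 0.0, None, out=data)
    return InterferometricStack(
        intensities=data,
        frame_rate_hz=fs_hz,
        camera=camera,
        optics=optics,
        truth_labels=labels,
        label_names=label_names,
    )


def simulate_tile_set(
    scene: np.ndarray,
    grid: tuple[int, int],
    tile_px: int,
    step_px: int,
    jitter_px: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TileSet:
    """Cut an overlapping tile grid out of ``scene`` with known offsets.

    Tiles sit on a regular lattice of pitch ``step_px``; every tile except the
    anchor (grid position 0,0) is perturbed by an integer jitter drawn
    uniformly from ``[-jitter_px, +jitter_px]`` per axis, emulating stage
    positioning error.  With ``noise_sd = 0`` and ``jitter_px = 0`` the
    overlap regions of neighbouring tiles are identical by construction.
    """
    scene = np.asarray(scene, dtype=np.float64)
    if scene.ndim != 2:
        raise GeometryError("scene must be a 2-D image")
    g_rows, g_cols = grid
    if g_rows < 1 or g_cols < 1:
        raise GeometryError("grid must be at least 1 x 1")
    if not 0 < step_px < tile_px:
        raise GeometryError("need 0 < step_px < tile_px for overlapping tiles")
    need_h = tile_px + (g_rows - 1) * step_px + 2 * jitter_px
    need_w = tile_px + (g_cols - 1) * step_px + 2 * jitter_px
    if need_h > scene.shape[0] or need_w > scene.shape[1]:
        raise GeometryError(
            f"scene {scene.shape} too small for grid {grid} with tile "
            f"{tile_px}, step {step_px}, jitter {jitter_px}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    margin = jitter_px
    tiles: list[np.ndarray] = []
    offsets = np.zeros((g_rows * g_cols, 2), dtype=np.int64)
    for gr in range(g_rows):
        for gc in range(g_cols):
            i = gr * g_cols + gc
            y = margin + gr * step_px
            x = margin + gc * step_px
            if i > 0 and jitter_px > 0:
                y += int(rng.integers(-jitter_px, jitter_px + 1))
                x += int(rng.integers(-jitter_px, jitter_px + 1))
            tile = scene[y : y + tile_px, x : x + tile_px].copy()
            if noise_sd > 0:
                tile += rng.normal(0.0, noise_sd, tile.shape)
            tiles.append(tile)
            offsets[i] = (y, x)
    return TileSet(
        tiles=tiles,
        true_offsets=offsets,
        grid_shape=(g_rows, g_cols),
        tile_px=tile_px,
        step_px=step_px,
        scene_shape=scene.shape,
    )


def _disk_footprint(center: tuple[int, int], area_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the ``area_px`` pixels nearest to ``center``.

    Taking exactly the requested number of nearest pixels makes each nucleus a
    near-circular blob of *exactly* the nominal per-cell area, so area-based
    counts are exact by construction.
    """
    radius = int(math.ceil(math.sqrt(area_px / math.pi))) + 1
    cy, cx = center
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = (yy**2 + xx**2).ravel()
    order = np.argsort(d2, kind="stable")[:area_px]
    return cy + yy.ravel()[order], cx + xx.ravel()[order]


def simulate_stained_zstack(
    n_cells: int,
    cell_area_px: int = 50,
    image_size: int = 256,
    n_planes: int = 5,
    fg_level: float = 200.0,
    bg_level: float = 50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    max_tries_per_cell: int = 500,
) -> StainedZStack:
    """Simulate a stained-nuclei z-stack with a known cell count.

    Nuclei are non-overlapping disk-like blobs of exactly ``cell_area_px``
    pixels at ``fg_level`` on a ``bg_level`` background, each drawn into one
    of ``n_planes`` planes; Gaussian noise is added everywhere.  The
    maximum-intensity projection has a bimodal histogram (background and
    foreground peaks), matching the assumption of the counting pipeline.
    """
    if n_cells < 0 or cell_area_px < 1 or n_planes < 1 or image_size < 1:
        raise SimulationParameterError("counts and sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    radius = math.sqrt(cell_area_px / math.pi)
    min_sep = 2.0 * radius + 3.0
    margin = int(math.ceil(radius)) + 2
    if 2 * margin >= image_size and n_cells > 0:
        raise PackingError("image_size too small for the requested cell area")

    centers: list[tuple[int, int]] = []
    for _ in range(n_cells):
        for attempt in range(max_tries_per_cell):
            cy = int(rng.integers(margin, image_size - margin))
            cx = int(rng.integers(margin, image_size - margin))
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers
            ):
                centers.append((cy, cx))
                break
        else:
            raise PackingError(
                f"could not place {n_cells} non-overlapping nuclei of "
                f"{cell_area_px} px in a {image_size}px image"
            )

    stack = np.full((n_planes, image_size, image_size), float(bg_level))
    planes = rng.integers(0, n_planes, size=n_cells)
    for (cy, cx), plane in zip(centers, planes):
        ys, xs = _disk_footprint((cy, cx), cell_area_px)
        stack[plane, ys, xs] = fg_level
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return StainedZStack(
        stack=stack,
        centers=np.array(centers, dtype=np.int64).reshape(n_cells, 2),
        planes=np.asarray(planes, dtype=np.int64),
        cell_area_px=cell_area_px,
        fg_level=fg_level,
        bg_level=bg_level,
    )


def quantize_counts(
    data: np.ndarray, full_scale: int = FULL_SCALE_COUNTS
) -> np.ndarray:
    """Round to integer counts and clip at the full-well count (16-bit)."""
    return np.clip(np.rint(data), 0, full_scale).astype(np.uint16)
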