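"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from dffoct import (
    MetricConfig,
    PixelDynamicsParams,
    compute_dynamic_image,
    simulate_phantom_stack,
)


@pytest.fixture(scope="session")
def textured_scene() -> np.ndarray:
    """Integer-valued random texture, ideal for exact-recovery checks."""
    rng = np.random.default_rng(1234)
    return rng.integers(0, 4096, size=(420, 420)).astype(np.float64)


@pytest.fixture(scope="session")
def two_regime_stack():
    """Phantom with a ~4 Hz and a ~10 Hz regime, 576 pixels each."""
    shape = (24, 48)
    left = np.zeros(shape, dtype=bool)
    left[:, :24] = True
    right = ~left
    slow = PixelDynamicsParams(regime_label="slow", target_mean_freq_hz=4.0)
    fast = PixelDynamicsParams(regime_label="fast", target_mean_freq_hz=10.0)
    return simulate_phantom_stack(
        [(left, slow), (right, fast)], shape, 512, 100.0, seed=20240917
    )


@pytest.fixture(scope="session")
def two_regime_metrics(two_regime_stack):
    return compute_dynamic_image(two_regime_stack, MetricConfig())


@pytest.fixture(scope="session")
def rpc_band_stack():
    """Phantom targeting the retinal-progenitor-like 5.5-8 Hz band."""
    shape = (24, 24)
    region = np.ones(shape, dtype=bool)
    params = PixelDynamicsParams(
        regime_label="rpc", target_mean_freq_hz=0.5 * (5.5 + 8.0)
    )
    return simulate_phantom_stack(
        [(region, params)], shape, 512, 100.0, seed=77
    )
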