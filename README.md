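# dffoct

Processing toolkit for **dynamic full-field optical coherence tomography
(D-FFOCT)** — a label-free microscopy in which the contrast at every camera
pixel comes from the temporal fluctuations of the interferometric signal,
reflecting subcellular (metabolic/organelle) activity in live 3-D samples
such as retinal organoids and explants.

The package is aimed at users of D-FFOCT modules and at anyone who needs a
desk-testable reference for the associated processing chain. It provides:

* **Per-pixel dynamic metrics** from a time series of interferometric images
  (default 512 frames at 100 Hz): the power-weighted mean frequency of the
  periodogram `f̄ = Σ f·P(f)/Σ P(f)`, its power-weighted spread
  `sqrt(Σ P·(f−f̄)²/Σ P)`, and the mean running standard deviation over a
  50-sample sliding window — rendered as a hue–saturation–brightness image
  (hue = 3–13 Hz mean frequency, blue→red; saturation = spectral
  narrowness; brightness = fluctuation amplitude).
* **Temporal binning** of 500 Hz acquisitions in groups of 5 frames into an
  effective 100 Hz series, with the √5 white-noise SNR gain.
* **Mosaic stitching** of stage-scanned overlapping tile grids: planning,
  integer-pixel normalized-cross-correlation registration, spanning-tree
  offset resolution, feathered blending.
* **Area-based cell counting** for stained z-stacks: maximum-intensity
  projection, two-peak histogram thresholding (minimal-overlap criterion),
  strict >25 px component filtering, counts from total area divided by a
  per-cell surface factor (50 px @ ×20, 200 px @ ×40), colocalization and
  marker/DAPI pixel ratios.
* **Acquisition-pipeline timing model**: closed forms and a discrete-event
  simulation of the parallelized acquire → transfer → process → save
  workflow, its feasibility conditions, steady-state per-image period, and
  speed-up over a sequential reference.
* **Synthetic phantoms with ground truth** (phase-diffusion interferometric
  stacks with tunable spectral content, overlapping tile sets, stained-nuclei
  z-stacks) so the whole chain is testable without an instrument.

## Worked example

```python
import numpy as np
from dffoct import (
    AcquisitionTiming, MetricConfig, PixelDynamicsParams,
    compute_dynamic_image, simulate_phantom_stack, speedup,
    steady_state_period,
)

# A 32x32 phantom: a disk of "retinal-progenitor-like" dynamics targeting
# the 5.5-8 Hz band, on a static noisy background.
yy, xx = np.mgrid[:32, :32]
disk = (yy - 16) ** 2 + (xx - 16) ** 2 < 10 ** 2
rpc = PixelDynamicsParams(regime_label="progenitor", target_mean_freq_hz=6.75)
stack = simulate_phantom_stack([(disk, rpc)], (32, 32),
                               n_frames=512, fs_hz=100.0, seed=0)

metrics = compute_dynamic_image(stack, MetricConfig())
inside = metrics.mean_frequency_hz[disk]
outside = metrics.mean_frequency_hz[~disk]
print(f"dynamic region: {np.median(inside):.2f} Hz median, "
      f"{((inside >= 5.5) & (inside <= 8)).mean():.0%} in 5.5-8 Hz")
print(f"background:     {np.median(outside):.2f} Hz median (noise-dominated)")

t = AcquisitionTiming()  # 512 frames @ 100 Hz; 0.79 / 1.34 / 0.53 s stages
print(f"steady-state period: {steady_state_period(t):.2f} s; "
      f"speed-up vs 50.5 s: {speedup(t, 50.5):.2f} (~{round(speedup(t, 50.5))}x)")
```

prints

```
dynamic region: 6.77 Hz median, 95% in 5.5-8 Hz
background:     25.07 Hz median (noise-dominated)
steady-state period: 5.12 s; speed-up vs 50.5 s: 9.86 (~10x)
```

The dynamic disk is recovered at its target mean frequency and would render
green/yellow in the 3–13 Hz hue band; the static background's spectrum is
flat noise, so its mean frequency sits at mid-Nyquist (25 Hz) with near-zero
amplitude — it renders black. The pipelined workflow delivers one dynamic
image per 5.12 s acquisition, ten times faster than the 50.5 s sequential
reference.

A CLI mirrors the library (`dffoct simulate stack|tiles|nuclei`,
`dffoct dynamics`, `dffoct stitch`, `dffoct count`, `dffoct schedule`); see
`dffoct --help`.

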