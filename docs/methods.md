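# Methods

## Dynamic contrast from interferometric time series

Dynamic full-field OCT (D-FFOCT) encodes subcellular activity in the temporal
fluctuations of the interferometric intensity recorded at every camera pixel.
For each pixel, a time series of `n_frames` samples (default 512) at sampling
rate `fs` (default 100 Hz) is reduced to three metrics:

* **Mean frequency** `f̄ = Σ f·P(f) / Σ P(f)` over the one-sided periodogram
  of the mean-removed series, excluding the DC bin. Units: Hz; range
  (0, fs/2].
* **Frequency spread** `sqrt(Σ P(f)·(f − f̄)² / Σ P(f))`, DC excluded. Units:
  Hz.
* **Amplitude**: the mean over all stride-1 sliding windows (default 50
  samples, sample standard deviation with the n−1 denominator, windows fully
  inside the series) of the in-window standard deviation. Units: camera
  counts.

The PSD estimator is a single mean-removed rectangular-window periodogram.
No Welch segmenting or tapering is applied: the metrics integrate over
frequency anyway, and segment averaging would only trade the frequency
resolution that the moments use. The density scaling satisfies Parseval
(`Σ P · Δf = sample variance`), which the tests assert at 1e-9 relative
tolerance. The DC bin is excluded from both moments because mean removal
drives it to ≈0 and its inclusion would only bias `f̄` toward zero. Moments
are computed over the full (0, fs/2] band; the 3–13 Hz band is a *display*
range applied at rendering only.

A pixel whose spectrum has no power above DC is flagged NaN ("no signal")
and rendered black.

### Vectorization contract

`compute_dynamic_image` transposes the stack to a time-last contiguous
layout and runs exactly the scalar operations as reductions over the inner
axis. Because every reduction (mean, FFT, weighted sums, windowed std) then
follows the same code path as the 1-D functions, the image result equals an
explicit per-pixel loop bit for bit; this is asserted on 16×16 crops.

### Temporal binning

Acquisitions at 500 Hz (2560 frames) are averaged in groups of
`bin_width = 5` consecutive frames, giving an effective 512-frame series at
100 Hz. For white noise the SNR (mean/std) improves by √k; the Monte-Carlo
check over 10⁴ series requires √5 within 2%. A non-divisible tail is
truncated with a warning rather than an error, since instruments commonly
deliver a few trailing frames.

### HSB rendering

* Hue: linear in mean frequency over `[hue_min, hue_max]` (default 3–13 Hz),
  clamped; the low end maps to blue (240°), the high end to red (0°).
* Saturation: `1 − spread/(fs/4)`, clipped to [0, 1]. The quarter-Nyquist
  scale is a convention chosen so that a spread of half the usable band
  fully desaturates; only the qualitative direction (narrowband ⇒ vivid) is
  prescribed by the display model.
* Brightness: amplitude normalised between global per-acquisition
  percentiles (default 1–99.9) and clipped to [0, 1]. Global rather than
  per-tile normalisation keeps longitudinal acquisitions comparable. A
  constant amplitude plane (e.g. all zero) renders black rather than
  erroring; a *configured* degenerate percentile pair is an error.

## Synthetic signal model

Full interferometric physics (coherence gating, defocus, refractive
structure) is out of scope; the generator reproduces the *statistics* the
processing consumes. Each pixel follows

    I(t) = baseline + A·cos(φ(t)) + n(t),

with `φ` a Brownian phase whose per-step increment variance is `2Δt/τ`. The
autocorrelation of `cos φ` is then `½·exp(−|t|/τ)`, i.e. a Lorentzian line
of half-width `1/(2πτ)` centred at DC, verified against an
ensemble-averaged DFT periodogram over 250 realizations. `n(t)` is additive
Gaussian camera noise.

Defaults emulate the nominal camera operating point: baseline at 95% of the
16-bit full well (62 258 counts), noise σ = 58 counts (shot-noise-limited
SNR ≈ 1071), fringe amplitude 2000 counts. Counts are kept real-valued
internally and quantized to uint16 (clipped at full well) only when writing
files.

**Frequency calibration.** A regime can be specified by a *target mean
frequency* rather than τ. The mapping is inverted numerically from the
expected finite-sample periodogram: the Bartlett-windowed transform of the
exact model autocovariance plus a flat `noise_sd²` floor, with the DC bin
excluded — a deterministic, Monte-Carlo-free oracle. Inversion uses a
bracketed root search on log τ (the mapping is strictly monotone) and is
cached. Targets are defined at the *analysis* condition (default 512 frames
at 100 Hz): a 500 Hz acquisition destined for bin-by-5 processing uses the
same regime definition, since the metric is computed on the binned series.
The residual bias from the binning filter's sinc response is small and
visible in tests only as a slight downward shift (~0.1–0.8 Hz near the top
of the band).

At this operating point the per-pixel mean-frequency estimate has a spread
of ~0.6 Hz (512 samples), so a regime targeted at the centre of the
5.5–8 Hz band is recovered in band for ≈95% of pixels.

**Reproducibility.** Every generator is a pure function of its seed. Phantom
stacks derive one RNG stream per pixel keyed on `(seed, row, col)`, so any
spatial subset reproduces identically regardless of the surrounding layout.

**What the phantoms do not emulate:** spatial correlations between pixels
(real organelle motion is spatially coherent), non-Gaussian shot noise,
photobleaching or drift, coherence-plane inhomogeneity across the field, and
non-Lorentzian line shapes. Passing tests therefore demonstrate correctness
of the *processing*, not biological fidelity of the contrast.

## Mosaicking

Tile lattices are planned with canvas extent `tile + (n−1)·step` per axis.
The printed canvas sizes of stage-scanned mosaics imply a step near 744 px
for 1440-px tiles rather than the nominal 50% overlap step of 720 px, and
are mutually inconsistent across grid sizes, so the step is an explicit
parameter and canvas sizes are treated as step-dependent.

Pairwise registration is an exhaustive integer-shift search (translation
only — appropriate for a stage-scanned lattice) maximizing the normalized
cross-correlation of the overlap; the correlation value is the confidence.
Overlaps smaller than 16 px or with zero variance fail softly: the nominal
shift is kept and flagged. Global positions are chained from the top-left
anchor along the maximum-confidence spanning tree of the pair graph —
deterministic and adequate for lattice grids; no global least-squares
refinement is attempted.

Blending uses separable linear-ramp feathering with integer-valued weights
normalised to sum to one at every covered pixel. Integer weights make the
convex combination of equal values exact in floating point, so assembling
noise-free tiles at true offsets reproduces the scene bit for bit — the
property the tests assert.

## Cell counting

The counting pipeline assumes a fluorescence z-stack whose
maximum-intensity projection separates into a background/noise mode and a
signal mode:

1. **MIP** across planes.
2. **Two-peak threshold.** The 256-bin histogram is smoothed with a 5-bin
   moving average. Peaks are detected on the log1p histogram with a minimum
   prominence ratio of 3 and minimum separation of 5 bins: in log space a
   small genuine signal peak above an empty valley is prominent, while
   Poisson ripples on a large unimodal background are not — this is what
   lets a blank image be rejected as unimodal while a single 50-pixel
   nucleus in a 512² image is still detected. A two-component Gaussian
   mixture (initialised at the two peaks) is fitted to the pixel values and
   the threshold is the intersection of the weighted component densities
   between the means, equivalently the point minimising total misclassified
   mass; if the fit degenerates the deepest inter-peak valley is used.
   Foreground is `I ≥ threshold`.
3. **Size discrimination.** 8-connected components with area strictly
   greater than 25 px are retained (strict, per the counting rule; the
   binarization itself is inclusive).
4. **Area-based count** = retained area / per-cell surface factor (50 px at
   ×20, 0.56 µm/px; 200 px at ×40, 0.26 µm/px — equivalent circles of
   radius 2.23 µm and 2.07 µm), rounded half away from zero.

Colocalization ANDs the per-channel binary masks first, then applies the
size filter and area division — the only causally consistent ordering, since
thresholding cannot follow binarization. Expression ratios against a
nuclear counterstain compare raw above-threshold pixel counts.

A projection with no detectable second peak yields an empty result with
count 0 at the pipeline level, while the scalar threshold operation raises,
so callers probing a single image still get a diagnostic.

Synthetic nuclei are the `cell_area_px` pixels nearest a centre (exactly
the nominal area, near-circular), non-overlapping by a minimum
centre-distance constraint with bounded rejection sampling. This makes the
pipeline's count exactly equal to the constructed count for 0, 1, 10, and
100 cells, which the tests require.

## Acquisition timing model

Four stages per batch — acquisition (`N·T_s`, 5.12 s for 512 frames at
100 Hz), transfer (0.79 s), GPU processing (1.34 s), saving (0.53 s) — with
one worker per stage and unbounded FIFO buffers. Sequential execution of
`n` batches takes `n·(N·T_s + t_p + t_gpu + t_save)`; the overlapped
pipeline takes `n·N·T_s + t_p + t_gpu + t_save` *when acquisition is the
slowest stage*. The discrete-event simulation is the general model: the
recurrence `end[b,s] = max(end[b,s−1], end[b−1,s]) + d_s`.

The three textbook chained inequalities (`N·T_s ≥ t_p`,
`N·T_s + t_p ≥ t_gpu`, `N·T_s + t_p + t_gpu ≥ t_save`) are reported
individually, but they are necessary rather than sufficient: a downstream
stage longer than the acquisition period eventually queues even when its
chained inequality holds (e.g. acquisition 1 s, transfer 1 s, processing
1.8 s). The exact validity condition, `acquisition ≥ max(other stages)`, is
reported as `closed_form_valid`, and `pipelined_time` falls back to the
simulation when it fails. Randomized paired evaluation over 1000 timings
checks closed form and simulation agree to 1e-9 s whenever the condition
holds.

The steady-state per-image period is the slowest stage's duration — 5.12 s
at the default operating point, versus a 50.5 s sequential per-image
reference: a speed-up of ≈9.86, reported rounded as 10. A `stall_s`
parameter adds a per-batch acquisition stall for slow-stepping stages on
free-floating samples (default 0).

## Problem sizes and numerical choices

* Phantom suites use 512-frame stacks with 100–576 pixels per regime;
  ensemble oracles use 250 realizations (line width) and 10⁴ series (SNR
  gain, c4 bias). These sizes give Monte-Carlo standard errors comfortably
  inside the asserted tolerances while the full suite runs in well under a
  minute.
* All RNG flows through `numpy.random.default_rng` with explicit seeds;
  hypothesis tests are bounded and seeded through their strategies.
* Degenerate inputs: zero-power spectra flag NaN; flat registration overlaps
  fail soft with the nominal shift; constant images raise on thresholding;
  blank stacks count zero at the pipeline level; binning tails truncate with
  a warning.

## Known limitations

* The phase-diffusion model produces DC-centred Lorentzian lines only; it
  cannot emulate oscillatory (peaked) spectra.
* Registration is integer-pixel and translation-only; no illumination
  flat-fielding is applied before correlation.
* The GMM threshold assumes approximately Gaussian histogram modes; heavily
  skewed foreground distributions fall back to the valley rule.
* The timing model ignores buffer limits and contention; it is a function of
  its inputs, not a hardware benchmark.
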