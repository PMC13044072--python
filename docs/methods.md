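# Methods

## The geometric band model

Band centers are generated by `f_n = f_ref · R^n` with `f_ref = 10.5` Hz
(the population-mean adult alpha rhythm, assigned index 0) and
`R = 1.7275` (Blagg's constant exponential spacing ratio, replacing the
coarse doubling of the original Titius–Bode rule). Adjacent bands are
separated at the geometric mean of their centers,
`f_sep = √(f_n · f_{n+1})`, which is the arithmetic midpoint of the
centers in log-frequency. Because every boundary is shared exactly
between its two neighbours, the bands partition `(0, ∞)` with no gaps or
overlaps; the lowest band is open below and the highest open above. The
whole construction is scale-equivariant: rescaling `f_ref` by `s`
rescales every center and boundary by `s`.

Intervals are lower-closed/upper-open `[lower, upper)`: a frequency that
falls exactly on a boundary belongs to the upper band (10.50 Hz is
alpha₂). This is an arbitrary but deterministic convention; published
range tables print touching intervals without assigning the shared
point.

The alpha band (`n = 0`) is subdivided at `f_ref` into alpha₁/alpha₂,
reflecting the functional lower/upper-alpha distinction. The sub-band
"centers" reported for alpha₁/alpha₂ are geometric means of their
limits — a display convenience; the model's alpha center remains
`f_ref`.

Default index range is −2…+3 (delta, theta, alpha₁/₂, beta, gamma₁,
gamma₂). Widening `n_max` extrapolates further gamma subdivisions
(`n = 4` → gamma₃, in the high-frequency-oscillation range); this is
available but not a default, since scalp EEG above ~45 Hz is
artifact-prone.

### Precision protocols

The engine always computes at full double precision. A separate
`rounding="paper"` protocol reproduces the published tables, whose
boundary values were derived from centers already rounded to 2 dp. Three
of those tabulated centers (6.07, 31.35, 54.21 Hz) differ by up to
0.08 Hz from direct 2-dp rounding of the exact values (6.08, 31.33,
54.13) — the original tabulation's rounding pipeline is not reproducible
from `R` alone — so the protocol keeps the canonical tabulated 2-dp
centers as data (`TABULATED_CENTERS_2DP`) for the default anchor/ratio
and falls back to `round(·, 2)` otherwise. Boundaries computed from
those rounded centers are kept at full precision and rounded only for
display: 4.62, 7.98, 13.80, 23.85, 41.22 Hz. (The alpha–beta separation
recomputes as 13.80 from the rounded centers, one unit in the last digit
below the commonly printed 13.81.)

The protocol matters for the headline alignment number below, so the
CLI `scheme` and `align` commands default to the replication protocol;
the library `build_scheme` defaults to full precision.

### Environmental alignment

`schumann_alignment` reports, for each reference mode (defaults: the
fundamental Schumann resonance 7.83 Hz and harmonics near 14.1, 20.3,
26.0, 33.0 Hz; configurable because the harmonic positions are only
known to ~±0.5 Hz), the nearest scheme feature — any band center or
closed boundary — and the deviation as a percentage of the mode
frequency, `100·|feature − mode|/mode`. The headline quantity is the
theta–alpha boundary against the fundamental mode:

* tabulated-rounding protocol: boundary `√(6.07·10.50) = 7.9834` Hz →
  **1.96 %** deviation (< 2 %);
* strict full precision: boundary `7.9888` Hz → **2.03 %**.

Both numbers are computed by the package and asserted in the tests; the
often-quoted "< 2 %" holds under the rounded-centers protocol only.
These deviations are descriptive; the package computes no coupling
statistic and makes no causal claim.

The classical comparator applies the original Titius–Bode multipliers
`0.4 + 0.3·2^m` with alpha anchored at `m = 1` (multiplier 1.0, the
"Earth" term): delta 0.4 (the degenerate `m → −∞` term), theta 0.7,
beta 1.6. This is the unique natural assignment that puts the classical
theta center at `0.7 × 10.5 = 7.35` Hz, about 6 % below 7.83 Hz
(signed deviation `100·(mode − center)/mode = 6.13 %`). The
`classical_tb` scheme preset realizes band intervals from these centers
with the same geometric-mean boundary rule; the classical rule itself
only supplies centers.

## Anchor estimation

Three anchor candidates are provided:

* `edge_geometric_mean(0.5, 100)` = 7.07 Hz — the log-center of the
  conventional EEG support;
* the same scaled by the golden ratio φ = 1.618 → 11.4 Hz;
* the individual alpha frequency (IAF), read off a PSD.

IAF estimation detrends the spectrum with a single straight-line
least-squares fit of log₁₀ power against log₁₀ frequency over the full
PSD support (the simplest aperiodic model; deliberately replaceable —
no knee term, no multitaper or model-based spectral parameterization),
then returns the most prominent local maximum of the residual within
the search window (default 7–14 Hz, bracketing both the classical alpha
range and the scheme's alpha₁/alpha₂ span). Prominence ties within a
1e-9 relative tolerance break toward the lower frequency, for
determinism. If no local maximum rises above the detrended baseline the
estimator raises a `NoPeakError` — never a silent default.

Known bias: for a Gaussian peak of width σ planted *additively in linear
power* on an `f^−β` background, the maximum of the log-domain residual
sits above the planted center by approximately `σ²β/f`. This is a
property of log-domain peak picking, not of the implementation; with
realistic alpha linewidths (σ ≈ 0.6 Hz, FWHM ≈ 1.4 Hz) the bias
(≲ 0.1 Hz) stays below the default 0.2 Hz grid step, and the test
battery verifies one-grid-step recovery across peak-to-background
ratios ≥ 3 and β ∈ [0.5, 2] on noise-free fixtures. With per-bin
multiplicative noise the argmax additionally jitters by more than one
bin for broad peaks; one-bin accuracy should not be expected on noisy
real spectra.

Re-anchoring replaces `f_ref` with the IAF and leaves `R` fixed;
whether `R` should also be refit per subject is an open modelling
question, and `estimate_geometric_ratio` exposes the refit route
separately.

## Band power and scheme comparison

Band power is the trapezoidal integral of the PSD restricted to each
band; a grid bin straddling a boundary is split by linear interpolation
of the PSD at the boundary frequency, which is exact for
piecewise-linear (trapezoid-consistent) spectra. Relative power divides
by the total over the covered support, so relative powers sum to 1
(±1e-9) whenever the support is covered. Open-ended bands are truncated
at the PSD grid limits or at an explicit cap. `compare_schemes` pairs
band-power tables from two schemes by label and reports the
relative-power difference; unmatched labels appear one-sided.

## Ratio conformity fitting

`estimate_geometric_ratio` fits `log f = log f_ref + n·log R` to peak
frequencies by least squares, after assigning each peak an integer index.
The assignment search rounds `log(f/f₀)/log R_init` over 64 log-spaced
anchor candidates `f₀` spanning `[min(peaks)/R_init, max(peaks)]`
(bounded, deterministic; assignments identical up to an index shift are
fitted once). The fit with the smallest RMS log-residual wins;
`R_hat = exp(slope)`. The anchor is identifiable only up to a power of
`R`, so indices are normalized to put index 0 nearest the peaks'
geometric center. Degenerate inputs (fewer than two distinct peaks, or
every assignment collapsing onto one index) raise errors. The RMS
log-residual is the conformity score: ~0 for geometric progressions,
strictly larger for, e.g., arithmetic ones. This least-squares
realization is one concrete definition of spectral-ratio conformity; it
is a package design choice, not a canonical formula.

Parameter recovery (verified in tests): with ≤2 % multiplicative jitter
on a 5-peak progression, the median relative error of `R_hat` over 100
seeded replicates is below 1 %.

## Synthetic fixtures

`synth_psd` builds `power(f) = A·f^−β + Σ aᵢ·exp(−(f−cᵢ)²/2σᵢ²)`,
optionally times log-normal noise `exp(σ_noise·z)` (multiplicative, so
positivity is preserved). Defaults emulate a typical adult resting
spectrum: `A = 20`, `β = 1`, one alpha peak (10.5 Hz, amplitude 15,
σ = 1 Hz), 5 % log-normal noise, 0.2 Hz grid over 1–45 Hz. All outputs
are bit-identical for a fixed seed. `synth_timeseries` renders peaks as
seeded-random-phase sinusoids and the background as spectrally shaped
white noise (exact target slope in expectation); `welch_psd` wraps
Hann-windowed Welch averaging and drops the DC bin so the grid is valid
for log-frequency methods.

What the generator does **not** emulate: multichannel structure, volume
conduction, non-stationarity, artifacts (eye-blink/EMG), spectral knees,
or asymmetric peak shapes. Passing tests therefore demonstrate
correctness of the operations under the stated spectral model, not
performance on clinical recordings.

## Problem sizes and numerical choices

All table quantities are closed-form; property suites use 10⁴-point
grids and 100-replicate seeded batteries, keeping the full test run
around a second. Tolerances: tessellation and classification are exact;
log-midpoint identity to 1e-12; index round-trips to 1e-9; band-power
conservation to 1e-9 relative. Degenerate inputs (non-positive
frequencies, misordered edges, empty PSD/scheme overlap, Nyquist
violations, sub-4-second simulations) raise typed errors
(`DomainError`, `ConfigurationError`) rather than warning or coercing.
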