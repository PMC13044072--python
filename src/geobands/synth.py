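"""Synthetic spectra and time series with known ground truth.

The generator emulates the broad structure of resting EEG power spectra: a
1/f^beta aperiodic background with Gaussian oscillatory peaks riding on it,
and optional multiplicative log-normal noise (which keeps the PSD
positive).  Every output is a deterministic function of the spec's seed, so
analysis operations can be tested against planted ground truth without any
recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as _signal

from .analysis import PSDTable
from .scheme import ConfigurationError

__all__ = ["SynthSpec", "synth_psd", "synth_timeseries", "welch_psd"]


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth description of a synthetic spectrum.

    ``peaks`` are (center Hz, amplitude in density units, sd Hz) triples.
    The background follows ``background_amp * f**-background_exp``;
    ``noise_sd`` is the sigma of multiplicative log-normal noise on the
    PSD.  Defaults describe a typical adult resting spectrum: a 1/f
    background with a single alpha peak at 10.5 Hz, sampled on a 0.2 Hz
    grid over 1-45 Hz.
    """

    background_amp: float = 20.0
    background_exp: float = 1.0
    peaks: tuple[tuple[float, float, float], ...] = ((10.5, 15.0, 1.0),)
    noise_sd: float = 0.05
    grid: tuple[float, float, int] = (1.0, 45.0, 221)
    seed: int = 0

    def __post_init__(self) -> None:
        f_min, f_max, n = self.grid
        if f_min <= 0 or f_max <= f_min or n < 8:
            raise ConfigurationError(f"invalid grid {self.grid}")
        if self.background_amp < 0 or self.noise_sd < 0:
            raise ConfigurationError("amplitudes and noise sd must be nonnegative")
        for c, a, sd in self.peaks:
            if c <= 0 or a < 0 or sd <= 0:
                raise ConfigurationError(f"invalid peak ({c}, {a}, {sd})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peaks"] = [list(p) for p in self.peaks]
        d["grid"] = list(self.grid)
        return d


def synth_psd(spec: SynthSpec) -> PSDTable:
    """Synthesize a PSD from its ground-truth spec.

    power(f) = background_amp * f**-beta + sum of Gaussian peaks, then
    multiplied by exp(noise_sd * z) with z ~ N(0, 1) drawn from the spec's
    seed.  Identical specs give bit-identical tables.
    """
    f_min, f_max, n = spec.grid
    freqs = np.linspace(f_min, f_max, n)
    power = spec.background_amp * freqs**-spec.background_exp
    for center, amp, sd in spec.peaks:
        power = power + amp * np.exp(-((freqs - center) ** 2) / (2.0 * sd**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        power = power * np.exp(spec.noise_sd * rng.standard_normal(n))
    return PSDTable(freqs=freqs, power=power, meta={"synth": spec.to_dict()})


def synth_timeseries(spec: SynthSpec, fs: float, duration: float) -> np.ndarray:
    """Synthesize a single-channel time series matching the spec.

    Peaks become sinusoids at their center frequencies (seeded random
    phases, amplitude proportional to the square root of the spec peak
    amplitude); the aperiodic background becomes 1/f^beta-shaped noise made
    by spectrally shaping seeded white noise, which hits the target
    log-log slope exactly in expectation.
    """
    if duration < 4.0:
        raise ConfigurationError("duration must be at least 4 s for stable spectra")
    if spec.peaks:
        f_nyq_needed = 2.0 * max(c for c, _, _ in spec.peaks)
        if fs <= f_nyq_needed:
            raise ConfigurationError(
                f"sampling rate {fs} Hz violates Nyquist for peaks up to "
                f"{f_nyq_needed / 2.0} Hz"
            )
    rng = np.random.default_rng(spec.seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for center, amp, _sd in spec.peaks:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + np.sqrt(amp) * np.sin(2.0 * np.pi * center * t + phase)
    if spec.background_amp > 0:
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-spec.background_exp / 2.0)
        pink = np.fft.irfft(spectrum * shape, n=n)
        rms = np.sqrt(np.mean(pink**2))
        if rms > 0:
            pink = pink / rms * np.sqrt(spec.background_amp)
        x = x + pink
    return x


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_length: int = 1024,
    overlap: float = 0.5,
) -> PSDTable:
    """Welch-averaged PSD: Hann-windowed overlapping segments.

    ``overlap`` is the fractional segment overlap in [0, 1).  For
    stationary signals the integrated density matches the signal variance
    to within the usual windowing losses.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("expected a 1-D signal")
    if segment_length > x.size:
        raise ConfigurationError(
            f"segment_length {segment_length} exceeds signal length {x.size}"
        )
    if not (0 <= overlap < 1):
        raise ConfigurationError("overlap must be in [0, 1)")
    freqs, power = _signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=segment_length,
        noverlap=int(overlap * segment_length),
        detrend=False,
    )
    # drop the DC bin so the grid is usable with log-frequency methods
    return PSDTable(freqs=freqs[1:], power=power[1:], meta={"welch_fs": fs})
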