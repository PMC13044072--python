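"""Apply band schemes to power spectra.

Covers frequency classification, band-power integration, scheme-vs-scheme
comparison, descriptive alignment of scheme features with environmental
reference frequencies (the Schumann resonance modes), and estimation of the
geometric spacing ratio from observed spectral peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .scheme import BandScheme, DomainError, ConfigurationError, DEFAULT_RATIO

__all__ = [
    "PSDTable",
    "PeakSet",
    "ModeAlignment",
    "AlignmentReport",
    "RatioFit",
    "NoPeakError",
    "classify_frequency",
    "band_power",
    "compare_schemes",
    "schumann_alignment",
    "classical_deviation",
    "aperiodic_detrend",
    "detect_peaks",
    "estimate_geometric_ratio",
    "SCHUMANN_MODES",
]

#: Fundamental Schumann resonance and its first four harmonics, Hz.
SCHUMANN_MODES: tuple[float, ...] = (7.83, 14.1, 20.3, 26.0, 33.0)


class NoPeakError(RuntimeError):
    """No spectral peak satisfies the detection criteria."""


@dataclass(frozen=True)
class PSDTable:
    """A sampled one-sided power spectral density.

    ``freqs`` is a strictly increasing Hz grid; ``power`` the nonnegative
    density values in arbitrary consistent units (e.g. uV^2/Hz).
    """

    freqs: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.ndim != 1 or freqs.shape != power.shape:
            raise ConfigurationError("freqs and power must be equal-length 1-D arrays")
        if freqs.size < 2:
            raise ConfigurationError("PSD needs at least two samples")
        if not np.all(np.diff(freqs) > 0):
            raise ConfigurationError("frequency grid must be strictly increasing")
        if np.any(~np.isfinite(power)) or np.any(power < 0):
            raise ConfigurationError("power values must be finite and nonnegative")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.freqs[0]), float(self.freqs[-1])

    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))


@dataclass(frozen=True)
class PeakSet:
    """Detected spectral peaks: frequency, amplitude (detrended log-power),
    and width in Hz."""

    freqs: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class ModeAlignment:
    mode_freq: float
    feature_kind: str  # "center" | "boundary"
    feature_label: str
    feature_freq: float
    percent_deviation: float


@dataclass(frozen=True)
class AlignmentReport:
    """Per-mode nearest scheme feature and percentage deviation.

    ``theta_alpha_deviation`` is the headline number: the deviation of the
    theta-alpha boundary from the first (fundamental) mode, in percent of
    the mode frequency.
    """

    rows: tuple[ModeAlignment, ...]
    theta_alpha_boundary: float | None
    theta_alpha_deviation: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mode_hz": r.mode_freq,
                    "feature_kind": r.feature_kind,
                    "feature_label": r.feature_label,
                    "feature_hz": r.feature_freq,
                    "percent_deviation": r.percent_deviation,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class RatioFit:
    """Least-squares geometric-progression fit to spectral peaks."""

    R_hat: float
    f_ref_hat: float
    residual_rms: float  # log-Hz units
    index_assignment: dict[float, int]


def classify_frequency(f: float, scheme: BandScheme) -> str:
    """Label of the band whose ``[lower, upper)`` interval contains ``f``."""
    return scheme.classify(f).label


def _integrate_interval(psd: PSDTable, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] with endpoints placed
    by linear interpolation (exact for piecewise-linear spectra)."""
    f, p = psd.freqs, psd.power
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fs = np.concatenate(([lo], f[inner], [hi]))
    ps = np.concatenate(([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]))
    return float(np.trapezoid(ps, fs))


def band_power(
    psd: PSDTable,
    scheme: BandScheme,
    f_max_cap: float | None = None,
) -> pd.DataFrame:
    """Absolute and relative power per band.

    Absolute power is the trapezoidal integral of the PSD restricted to
    each band interval; bins straddling a boundary are split by linear
    interpolation.  Relative power divides by the total over the covered
    support.  Open-ended bands are truncated at the PSD grid limits, or at
    ``f_max_cap`` if given.

    Returns a DataFrame with columns ``label``, ``lower``, ``upper``,
    ``absolute_power``, ``relative_power``.
    """
    f_lo, f_hi = psd.support
    cap = f_hi if f_max_cap is None else min(f_max_cap, f_hi)
    cover_lo = max(f_lo, scheme.bands[0].lower)
    cover_hi = min(cap, scheme.bands[-1].upper)
    if cover_hi <= cover_lo:
        raise DomainError(
            "PSD support does not overlap the scheme's frequency coverage"
        )
    rows = []
    for band in scheme.bands:
        lo = max(band.lower, f_lo)
        hi = min(band.upper, cap)
        rows.append(
            {
                "label": band.label,
                "lower": lo,
                "upper": hi if hi > lo else lo,
                "absolute_power": _integrate_interval(psd, lo, hi),
            }
        )
    out = pd.DataFrame(rows)
    total = _integrate_interval(psd, cover_lo, cover_hi)
    if total <= 0:
        out["relative_power"] = 0.0
    else:
        out["relative_power"] = out["absolute_power"] / total
    return out


def compare_schemes(
    psd: PSDTable,
    scheme_a: BandScheme,
    scheme_b: BandScheme,
    f_max_cap: float | None = None,
) -> pd.DataFrame:
    """Band powers under two schemes, paired by band label.

    Matched labels get ``relative_power_diff`` = a minus b; labels present
    in only one scheme are reported one-sided with NaN on the other side.
    """
    a = band_power(psd, scheme_a, f_max_cap).set_index("label")
    b = band_power(psd, scheme_b, f_max_cap).set_index("label")
    merged = a.join(b, how="outer", lsuffix="_a", rsuffix="_b")
    merged["relative_power_diff"] = (
        merged["relative_power_a"] - merged["relative_power_b"]
    )
    order = list(dict.fromkeys(list(a.index) + list(b.index)))
    return merged.loc[order].reset_index()


def schumann_alignment(
    scheme: BandScheme,
    modes: tuple[float, ...] | list[float] = SCHUMANN_MODES,
) -> AlignmentReport:
    """Nearest scheme feature (center or closed boundary) to each
    environmental reference mode, with percentage deviation of the mode.

    Deviation is ``100 * |feature - mode| / mode``.  The headline field
    reports the theta-alpha boundary against the first mode.
    """
    if not modes:
        raise ConfigurationError("mode list must not be empty")
    if any(m <= 0 for m in modes):
        raise DomainError("reference modes must be positive")
    feats = scheme.features()
    rows = []
    for mode in modes:
        kind, label, freq = min(feats, key=lambda t: abs(t[2] - mode))
        rows.append(
            ModeAlignment(
                mode_freq=float(mode),
                feature_kind=kind,
                feature_label=label,
                feature_freq=freq,
                percent_deviation=100.0 * abs(freq - mode) / mode,
            )
        )
    ta = scheme.boundary_between(-1, 0)
    ta_dev = None if ta is None else 100.0 * abs(ta - modes[0]) / modes[0]
    return AlignmentReport(
        rows=tuple(rows), theta_alpha_boundary=ta, theta_alpha_deviation=ta_dev
    )


def classical_deviation(f_ref: float, mode: float = 7.83) -> float:
    """Signed percent deviation of the classical Titius-Bode theta center
    (0.7 * f_ref) below a reference mode: ``100 * (mode - center) / mode``.

    Positive means the classical center sits below the mode.
    """
    if f_ref <= 0 or mode <= 0:
        raise DomainError("f_ref and mode must be positive")
    theta = 0.7 * f_ref
    return 100.0 * (mode - theta) / mode


# ---------------------------------------------------------------------------
# Peak-based estimation


def aperiodic_detrend(psd: PSDTable) -> np.ndarray:
    """Residual log10-power after removing the aperiodic 1/f trend.

    The trend is a single straight line fit by least squares to log-power
    vs log-frequency over the full PSD support.  Zero-power bins are
    floored to a tiny positive value before taking logs.
    """
    f = psd.freqs
    if f[0] <= 0:
        raise DomainError("detrending requires a strictly positive frequency grid")
    p = np.maximum(psd.power, np.finfo(float).tiny)
    logf = np.log10(f)
    logp = np.log10(p)
    slope, intercept = np.polyfit(logf, logp, 1)
    return logp - (intercept + slope * logf)


def detect_peaks(psd: PSDTable, min_prominence: float = 0.05) -> PeakSet:
    """Local maxima of the 1/f-detrended log-power spectrum.

    ``min_prominence`` is in detrended log10-power units.  Raises
    :class:`NoPeakError` when nothing qualifies.
    """
    resid = aperiodic_detrend(psd)
    idx, props = _signal.find_peaks(resid, prominence=min_prominence)
    idx = idx[resid[idx] > 0]  # must rise above the aperiodic baseline
    if idx.size == 0:
        raise NoPeakError("no spectral peak above the detrended baseline")
    proms = _signal.peak_prominences(resid, idx)[0]
    widths_samples = _signal.peak_widths(resid, idx, rel_height=0.5)[0]
    df = float(np.median(np.diff(psd.freqs)))
    return PeakSet(
        freqs=psd.freqs[idx],
        amplitudes=resid[idx],
        widths=widths_samples * df,
    )


def estimate_geometric_ratio(
    peaks: PeakSet | "np.ndarray | list[float]",
    R_init: float = DEFAULT_RATIO,
    n_candidates: int = 64,
) -> RatioFit:
    """Fit a geometric progression ``f = f_ref * R**n`` to peak frequencies.

    Each peak is assigned a candidate integer index by rounding its
    log-ratio index against a grid of ``n_candidates`` log-spaced anchor
    candidates spanning ``[min(peaks)/R_init, max(peaks)]``; every distinct
    assignment is fit by least squares in log-frequency, and the fit with
    the smallest RMS log-residual wins.  ``R_hat`` is the exponential of
    the fitted slope.

    The anchor is only identifiable up to a power of ``R`` (shifting every
    index by one rescales ``f_ref`` by ``R``); the returned indices are
    normalized so that index 0 sits nearest the peaks' geometric center,
    making ``f_ref_hat`` the fitted frequency closest to mid-spectrum.
    """
    if isinstance(peaks, PeakSet):
        freqs = np.asarray(peaks.freqs, dtype=float)
    else:
        freqs = np.asarray(peaks, dtype=float)
    freqs = np.unique(freqs)
    if freqs.size < 2:
        raise DomainError("need at least two distinct peak frequencies")
    if np.any(freqs <= 0):
        raise DomainError("peak frequencies must be positive")
    if R_init <= 1:
        raise DomainError("R_init must exceed 1")

    logf = np.log(freqs)
    logR0 = math.log(R_init)
    candidates = np.exp(
        np.linspace(math.log(freqs[0] / R_init), math.log(freqs[-1]), n_candidates)
    )
    seen: set[tuple[int, ...]] = set()
    best: RatioFit | None = None
    for f0 in candidates:
        ns = np.rint((logf - math.log(f0)) / logR0).astype(int)
        key = tuple(ns - ns[0])  # assignments equal up to an index shift fit alike
        if key in seen:
            continue
        seen.add(key)
        if np.unique(ns).size < 2:
            continue
        slope, intercept = np.polyfit(ns, logf, 1)
        resid = logf - (intercept + slope * ns)
        rms = float(np.sqrt(np.mean(resid**2)))
        if slope <= 0:
            continue
        if best is None or rms < best.residual_rms:
            shift = int(round((float(np.mean(logf)) - intercept) / slope))
            best = RatioFit(
                R_hat=float(math.exp(slope)),
                f_ref_hat=float(math.exp(intercept + slope * shift)),
                residual_rms=rms,
                index_assignment={
                    float(f): int(n - shift) for f, n in zip(freqs, ns)
                },
            )
    if best is None:
        raise DomainError(
            "degenerate peak set: every candidate assignment collapses to one index"
        )
    return best
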