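"""Candidate reference (anchor) frequencies for a band scheme.

Three routes are provided: the geometric mean of the spectrum edges, the
same scaled by the golden ratio, and a data-driven individual alpha
frequency (IAF) read off a power spectrum.  Any of them can re-anchor a
geometric scheme by replacing ``f_ref``; the spacing ratio ``R`` is left
untouched unless the caller refits it separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .analysis import PSDTable, NoPeakError, aperiodic_detrend
from .scheme import DomainError

__all__ = [
    "AnchorEstimate",
    "GOLDEN_RATIO",
    "edge_geometric_mean",
    "golden_ratio_reference",
    "estimate_iaf",
]

GOLDEN_RATIO = 1.618

#: Prominence ties closer than this (relative) are broken toward the lower
#: frequency; floating-point prominences are never exactly equal.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class AnchorEstimate:
    """A candidate scheme anchor frequency.

    ``quality`` is the peak prominence in detrended log10-power units for
    the data-driven method and 0 for analytic ones.
    """

    value: float
    method: str  # fixed | edge_geometric_mean | golden_ratio | iaf_peak
    search_window: tuple[float, float] | None = None
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DomainError("anchor frequency must be positive")
        if self.method == "iaf_peak" and self.search_window is not None:
            lo, hi = self.search_window
            if not (lo <= self.value <= hi):
                raise DomainError("IAF estimate fell outside its search window")


def edge_geometric_mean(f_low: float, f_high: float) -> float:
    """Geometric mean of the spectrum edges, sqrt(f_low * f_high).

    With the conventional EEG support 0.5-100 Hz this gives ~7.07 Hz, the
    logarithmic center of the spectrum.
    """
    if f_low <= 0 or f_high <= 0:
        raise DomainError("spectrum edges must be positive")
    if f_low > f_high:
        raise DomainError("edges must satisfy f_low <= f_high")
    return math.sqrt(f_low * f_high)


def golden_ratio_reference(
    f_low: float, f_high: float, phi: float = GOLDEN_RATIO
) -> float:
    """Edge geometric mean scaled by the golden ratio.

    For 0.5-100 Hz and phi = 1.618 this yields ~11.4 Hz, close to the
    population-mean alpha anchor.
    """
    if phi <= 0:
        raise DomainError("phi must be positive")
    return edge_geometric_mean(f_low, f_high) * phi


def estimate_iaf(
    psd: PSDTable, window: tuple[float, float] = (7.0, 14.0)
) -> AnchorEstimate:
    """Individual alpha frequency: the most prominent local maximum of the
    1/f-detrended PSD within ``window``.

    The aperiodic trend is a straight-line log-log fit over the full PSD
    support, subtracted before peak picking.  Equal-prominence ties go to
    the lower frequency.  Raises :class:`NoPeakError` when no local maximum
    rises above the detrended baseline inside the window — never a silent
    default.
    """
    lo, hi = window
    if not (0 < lo < hi):
        raise DomainError(f"invalid IAF window {window}")
    in_win = (psd.freqs >= lo) & (psd.freqs <= hi)
    if int(in_win.sum()) < 5:
        raise DomainError(
            f"PSD grid has only {int(in_win.sum())} samples in {window}; need >= 5"
        )
    resid = aperiodic_detrend(psd)
    idx, _ = _signal.find_peaks(resid)
    idx = idx[(psd.freqs[idx] >= lo) & (psd.freqs[idx] <= hi)]
    idx = idx[resid[idx] > 0]
    if idx.size == 0:
        raise NoPeakError(f"no alpha peak above the aperiodic baseline in {window}")
    proms = _signal.peak_prominences(resid, idx)[0]
    best = float(np.max(proms))
    tied = idx[proms >= best * (1.0 - _TIE_RTOL)]
    pick = int(tied.min())  # lowest frequency among (near-)equal prominences
    prominence = float(proms[np.flatnonzero(idx == pick)[0]])
    return AnchorEstimate(
        value=float(psd.freqs[pick]),
        method="iaf_peak",
        search_window=(float(lo), float(hi)),
        quality=prominence,
    )
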