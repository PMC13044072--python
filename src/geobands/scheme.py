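"""Geometric band schemes for the EEG frequency axis.

A scheme is generated by an exponential law for band centers,

    f_n = f_ref * R**n,

with an anchor frequency ``f_ref`` (the adult mean alpha rhythm, 10.5 Hz by
default) at index ``n = 0`` and a constant band-to-band ratio ``R`` (Blagg's
refinement of the Titius-Bode spacing constant, 1.7275 by default).
Boundaries between adjacent bands sit at the geometric mean of their
centers, i.e. the midpoint on a log-frequency axis, so the bands tessellate
the axis with no gaps and no overlaps.  The alpha band (n = 0) may be
subdivided into alpha1/alpha2 meeting exactly at ``f_ref``.

Bands are lower-closed / upper-open ``[lower, upper)``; the lowest band is
open below (lower limit 0) and the highest open above (upper limit +inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Band",
    "BandScheme",
    "DomainError",
    "ConfigurationError",
    "center_frequency",
    "index_of",
    "boundary",
    "build_scheme",
    "classical_tb_centers",
    "traditional_scheme",
    "classical_tb_scheme",
    "DEFAULT_F_REF",
    "DEFAULT_RATIO",
    "DEFAULT_LABELS",
]

DEFAULT_F_REF = 10.5
DEFAULT_RATIO = 1.7275

#: Default band names by index for the canonical six-band layout.
DEFAULT_LABELS: dict[int, str] = {
    -2: "delta",
    -1: "theta",
    0: "alpha",
    1: "beta",
    2: "gamma1",
    3: "gamma2",
}

#: Conventionally tabulated 2-dp center frequencies for the default scheme
#: (f_ref = 10.5, R = 1.7275, n = -2..3).  Three entries (6.07, 31.35,
#: 54.21) differ by up to 0.08 Hz from direct 2-dp rounding of the
#: full-precision centers (6.08, 31.33, 54.13); the published tabulation's
#: rounding pipeline is not reproducible from R alone, so these values are
#: kept as the canonical rounded inputs for table replication.
TABULATED_CENTERS_2DP: dict[int, float] = {
    -2: 3.52,
    -1: 6.07,
    0: 10.50,
    1: 18.14,
    2: 31.35,
    3: 54.21,
}

#: Classical Titius-Bode multipliers 0.4 + 0.3 * 2**m, with the alpha band
#: anchored at m = 1 (multiplier 1.0, the "Earth" term) and delta at the
#: degenerate m -> -inf term (multiplier 0.4).
CLASSICAL_TB_MULTIPLIERS: tuple[tuple[str, float], ...] = (
    ("delta", 0.4),
    ("theta", 0.7),
    ("alpha", 1.0),
    ("beta", 1.6),
)


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """A scheme or request is internally inconsistent."""


def center_frequency(f_ref: float, R: float, n: float) -> float:
    """Band-center frequency ``f_ref * R**n``.

    Parameters
    ----------
    f_ref : float
        Anchor frequency in Hz (> 0), assigned index 0.
    R : float
        Band-to-band scaling ratio (> 0).
    n : float
        Band index; integer for canonical bands, real values allowed for
        continuous placement on the geometric ladder.
    """
    if f_ref <= 0 or R <= 0:
        raise DomainError(f"f_ref and R must be positive, got f_ref={f_ref}, R={R}")
    return f_ref * R**n


def index_of(f: float, f_ref: float, R: float) -> float:
    """Real-valued band index of ``f``: ``log(f / f_ref) / log(R)``.

    Exact inverse of :func:`center_frequency`; locates any observed
    frequency on the geometric ladder.
    """
    if f <= 0:
        raise DomainError(f"frequency must be positive, got {f}")
    if f_ref <= 0:
        raise DomainError(f"f_ref must be positive, got {f_ref}")
    if R <= 1:
        raise DomainError(f"R must exceed 1, got {R}")
    return math.log(f / f_ref) / math.log(R)


def boundary(f_lower_center: float, f_upper_center: float) -> float:
    """Separation frequency between two adjacent band centers.

    The geometric mean ``sqrt(f_lower_center * f_upper_center)``: the
    midpoint of the two centers on a logarithmic frequency axis.
    """
    if f_lower_center <= 0 or f_upper_center <= 0:
        raise DomainError("band centers must be positive")
    if f_lower_center > f_upper_center:
        raise DomainError("centers must be ordered: lower <= upper")
    return math.sqrt(f_lower_center * f_upper_center)


@dataclass(frozen=True)
class Band:
    """One labeled frequency interval ``[lower, upper)``.

    ``lower == 0`` marks a band open below; ``upper == inf`` open above.
    """

    label: str
    n: int
    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.center < self.upper):
            raise ConfigurationError(
                f"band {self.label!r}: need lower < center < upper, "
                f"got {self.lower}, {self.center}, {self.upper}"
            )

    def contains(self, f: float) -> bool:
        return self.lower <= f < self.upper

    @property
    def open_below(self) -> bool:
        return self.lower == 0.0

    @property
    def open_above(self) -> bool:
        return math.isinf(self.upper)


@dataclass(frozen=True)
class BandScheme:
    """An ordered, contiguous set of labeled frequency bands.

    Geometric schemes built by :func:`build_scheme` carry their generating
    parameters (``f_ref``, ``R``, index range); hand-specified schemes such
    as the traditional preset may leave them ``None``.
    """

    bands: tuple[Band, ...]
    f_ref: float | None = None
    R: float | None = None
    n_min: int | None = None
    n_max: int | None = None
    subdivide_alpha: bool = False
    name: str = "scheme"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("scheme needs at least one band")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper != b.lower:
                raise ConfigurationError(
                    f"bands {a.label!r} and {b.label!r} do not tessellate: "
                    f"{a.upper} != {b.lower}"
                )

    # -- queries ---------------------------------------------------------

    def classify(self, f: float) -> Band:
        """The unique band whose ``[lower, upper)`` interval contains ``f``."""
        if f <= 0:
            raise DomainError(f"frequency must be positive, got {f}")
        for band in self.bands:
            if band.contains(f):
                return band
        raise DomainError(
            f"{f} Hz is outside this scheme's coverage "
            f"[{self.bands[0].lower}, {self.bands[-1].upper})"
        )

    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def centers(self) -> list[tuple[str, float]]:
        return [(b.label, b.center) for b in self.bands]

    def closed_boundaries(self) -> list[tuple[str, float]]:
        """Finite band edges, labeled ``lower_band/upper_band``."""
        out = []
        for a, b in zip(self.bands, self.bands[1:]):
            out.append((f"{a.label}/{b.label}", a.upper))
        first, last = self.bands[0], self.bands[-1]
        if first.lower > 0:
            out.insert(0, (f"<{first.label}", first.lower))
        if not math.isinf(last.upper):
            out.append((f"{last.label}>", last.upper))
        return out

    def features(self) -> list[tuple[str, str, float]]:
        """All (kind, label, Hz) scheme features: centers and closed boundaries."""
        feats = [("center", lab, f) for lab, f in self.centers()]
        feats += [("boundary", lab, f) for lab, f in self.closed_boundaries()]
        return feats

    def boundary_between(self, n_low: int, n_high: int) -> float | None:
        """The separation frequency between the last band of index ``n_low``
        and the first band of index ``n_high``, or None if absent."""
        for a, b in zip(self.bands, self.bands[1:]):
            if a.n == n_low and b.n == n_high:
                return a.upper
        return None

    def scaled(self, s: float) -> "BandScheme":
        """The scheme with every frequency multiplied by ``s > 0``."""
        if s <= 0:
            raise DomainError("scale factor must be positive")
        bands = tuple(
            replace(b, center=b.center * s, lower=b.lower * s, upper=b.upper * s)
            for b in self.bands
        )
        f_ref = None if self.f_ref is None else self.f_ref * s
        return replace(self, bands=bands, f_ref=f_ref)


def _label_for(n: int, labels: dict[int, str], subdivided: bool) -> str:
    if n in labels:
        return labels[n]
    if n > 3:
        return f"gamma{n - 1}"
    return f"n{n:+d}"


def build_scheme(
    f_ref: float = DEFAULT_F_REF,
    R: float = DEFAULT_RATIO,
    n_min: int = -2,
    n_max: int = 3,
    subdivide_alpha: bool = True,
    labels: dict[int, str] | None = None,
    rounding: str = "full",
) -> BandScheme:
    """Construct a geometric band scheme.

    Centers come from ``f_ref * R**n`` for ``n`` in ``[n_min, n_max]``;
    interior boundaries are geometric means of adjacent centers; the lowest
    band is open below and the highest open above.  With ``subdivide_alpha``
    the ``n = 0`` band is split into two sub-bands meeting exactly at
    ``f_ref``.

    ``rounding`` selects the precision protocol: ``"full"`` keeps every
    intermediate at double precision; ``"paper"`` feeds the geometric-mean
    step 2-dp-rounded centers (the canonical tabulated values
    :data:`TABULATED_CENTERS_2DP` when the default anchor and ratio are
    used), reproducing published boundary tables that were derived from
    already-rounded centers.  Boundaries themselves stay at full precision;
    round for display.
    """
    if n_min >= n_max:
        raise ConfigurationError(f"need n_min < n_max, got {n_min}, {n_max}")
    if R <= 1:
        raise DomainError(f"R must exceed 1, got {R}")
    if rounding not in ("full", "paper"):
        raise ConfigurationError(f"unknown rounding mode {rounding!r}")
    if labels is None:
        labels = DEFAULT_LABELS
    else:
        expected = n_max - n_min + 1
        if len(labels) != expected:
            raise ConfigurationError(
                f"label map has {len(labels)} entries for {expected} indices"
            )

    ns = list(range(n_min, n_max + 1))
    centers = [center_frequency(f_ref, R, n) for n in ns]
    if rounding == "paper":
        canonical = (f_ref == DEFAULT_F_REF) and (R == DEFAULT_RATIO)
        centers = [
            TABULATED_CENTERS_2DP[n]
            if canonical and n in TABULATED_CENTERS_2DP
            else round(c, 2)
            for n, c in zip(ns, centers)
        ]
    cuts = [boundary(a, b) for a, b in zip(centers, centers[1:])]
    lowers = [0.0] + cuts
    uppers = cuts + [math.inf]

    bands: list[Band] = []
    for n, c, lo, hi in zip(ns, centers, lowers, uppers):
        base = _label_for(n, labels, subdivide_alpha)
        if subdivide_alpha and n == 0:
            split = round(f_ref, 2) if rounding == "paper" else f_ref
            bands.append(Band(f"{base}1", n, boundary(lo, split), lo, split))
            bands.append(Band(f"{base}2", n, boundary(split, hi), split, hi))
        else:
            bands.append(Band(base, n, c, lo, hi))

    return BandScheme(
        bands=tuple(bands),
        f_ref=f_ref,
        R=R,
        n_min=n_min,
        n_max=n_max,
        subdivide_alpha=subdivide_alpha,
        name="tbb" if rounding == "full" else "tbb-paper-rounded",
    )


def classical_tb_centers(f_ref: float = DEFAULT_F_REF) -> list[tuple[str, float]]:
    """Band centers under the classical Titius-Bode progression.

    The classical spacing rule 0.4 + 0.3 * 2**m, anchored so that alpha
    corresponds to the m = 1 term (multiplier 1.0): theta gets 0.7 (m = 0),
    delta the degenerate 0.4 term, beta 1.6 (m = 2).  With ``f_ref`` = 10.5
    this places the theta center at 7.35 Hz.
    """
    if f_ref <= 0:
        raise DomainError(f"f_ref must be positive, got {f_ref}")
    return [(label, mult * f_ref) for label, mult in CLASSICAL_TB_MULTIPLIERS]


#: Traditional band ranges (Hz) as commonly tabulated: closed outer limits.
_TRADITIONAL_RANGES: tuple[tuple[str, int, float, float], ...] = (
    ("delta", -2, 1.0, 4.0),
    ("theta", -1, 4.0, 8.0),
    ("alpha1", 0, 8.0, 10.0),
    ("alpha2", 0, 10.0, 13.0),
    ("beta", 1, 13.0, 30.0),
    ("gamma", 2, 30.0, 100.0),
)


def traditional_scheme() -> BandScheme:
    """The conventional segmentation (delta 1-4, theta 4-8, alpha1 8-10,
    alpha2 10-13, beta 13-30, gamma 30-100 Hz).

    Centers are geometric means of the limits; coverage is the finite
    interval [1, 100) Hz.
    """
    bands = tuple(
        Band(label, n, math.sqrt(lo * hi), lo, hi)
        for label, n, lo, hi in _TRADITIONAL_RANGES
    )
    return BandScheme(bands=bands, name="traditional")


def classical_tb_scheme(f_ref: float = DEFAULT_F_REF) -> BandScheme:
    """A band scheme from the classical Titius-Bode centers.

    The classical rule only supplies centers; intervals are realized with
    the same geometric-mean boundary construction used for geometric
    schemes, open-ended at both extremes.
    """
    centers = classical_tb_centers(f_ref)
    cuts = [boundary(a[1], b[1]) for a, b in zip(centers, centers[1:])]
    lowers = [0.0] + cuts
    uppers = cuts + [math.inf]
    bands = tuple(
        Band(label, n, c, lo, hi)
        for (label, c), n, lo, hi in zip(centers, range(-2, 2), lowers, uppers)
    )
    return BandScheme(bands=bands, f_ref=f_ref, name="classical_tb")
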