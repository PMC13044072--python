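"""Plain-text readers and writers: PSD CSV tables and scheme JSON."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import PSDTable
from .scheme import Band, BandScheme, ConfigurationError

__all__ = [
    "read_psd_csv",
    "write_psd_csv",
    "scheme_to_dict",
    "scheme_from_dict",
    "write_scheme_json",
    "read_scheme_json",
    "PSD_CSV_HEADER",
]

PSD_CSV_HEADER = ("frequency_hz", "power")


class PSDParseError(ValueError):
    """A PSD CSV file failed validation; the message names the offending row."""


def read_psd_csv(path: str | Path) -> PSDTable:
    """Read a two-column ``frequency_hz,power`` CSV into a PSDTable.

    Rejects non-numeric cells, NaN or negative power, and non-increasing
    frequency grids, naming the first offending data row (1-based).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PSDParseError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    df.columns = PSD_CSV_HEADER
    for col in PSD_CSV_HEADER:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise PSDParseError(
                f"{path}: non-numeric or missing {col} at data row {bad[0] + 1}"
            )
        df[col] = vals
    neg = df.index[df["power"] < 0]
    if len(neg):
        raise PSDParseError(f"{path}: negative power at data row {neg[0] + 1}")
    diffs = np.diff(df["frequency_hz"].to_numpy())
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2
        raise PSDParseError(
            f"{path}: frequency grid not strictly increasing at data row {row}"
        )
    return PSDTable(
        freqs=df["frequency_hz"].to_numpy(),
        power=df["power"].to_numpy(),
        meta={"source": str(path)},
    )


def write_psd_csv(psd: PSDTable, path: str | Path) -> None:
    pd.DataFrame(
        {"frequency_hz": psd.freqs, "power": psd.power}
    ).to_csv(path, index=False)


def scheme_to_dict(scheme: BandScheme) -> dict:
    """JSON-ready mapping; open band limits serialize as null."""
    return {
        "f_ref": scheme.f_ref,
        "R": scheme.R,
        "n_min": scheme.n_min,
        "n_max": scheme.n_max,
        "subdivide_alpha": scheme.subdivide_alpha,
        "name": scheme.name,
        "bands": [
            {
                "label": b.label,
                "n": b.n,
                "center": b.center,
                "lower": None if b.lower == 0.0 else b.lower,
                "upper": None if math.isinf(b.upper) else b.upper,
            }
            for b in scheme.bands
        ],
    }


def scheme_from_dict(d: dict) -> BandScheme:
    try:
        bands = tuple(
            Band(
                label=b["label"],
                n=int(b["n"]),
                center=float(b["center"]),
                lower=0.0 if b["lower"] is None else float(b["lower"]),
                upper=math.inf if b["upper"] is None else float(b["upper"]),
            )
            for b in d["bands"]
        )
        return BandScheme(
            bands=bands,
            f_ref=d.get("f_ref"),
            R=d.get("R"),
            n_min=d.get("n_min"),
            n_max=d.get("n_max"),
            subdivide_alpha=bool(d.get("subdivide_alpha", False)),
            name=d.get("name", "scheme"),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed scheme JSON: {exc}") from exc


def write_scheme_json(scheme: BandScheme, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scheme_to_dict(scheme), indent=2) + "\n")


def read_scheme_json(path: str | Path) -> BandScheme:
    """Read and validate a scheme; tessellation violations raise."""
    return scheme_from_dict(json.loads(Path(path).read_text()))
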