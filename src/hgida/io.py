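"""CSV reading/writing for titrations, gradients, histograms and tables.

Dialect: comma-separated, dot decimal, mandatory header row.  All
concentrations in files are mol/L unless ``units='uM'`` is passed, in
which case the varied/total columns are rescaled by 1e-6 on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .photophysics import DecayHistogram, GradSeries
from .titration import TitrationSeries

__all__ = [
    "read_titration",
    "write_titration",
    "read_grad_series",
    "read_histogram",
    "read_thermo_table",
    "write_meta",
]

_CONC_COL = "varied_total_M"
_PH_COL = "pH"
_SIGNAL_COL = "signal"
_UNIT_SCALE = {"M": 1.0, "uM": 1e-6}


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        # round_trip parsing keeps write->read lossless at full precision
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    if col not in df.columns:
        raise ValidationError(f"{path}: missing required column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()] + 2  # header is line 1
    if len(bad):
        raise ValidationError(
            f"{path}: non-numeric value in column {col!r} at line(s) {list(bad)}"
        )
    if vals.isna().any():
        rows = list(vals.index[vals.isna()] + 2)
        raise ValidationError(f"{path}: empty cells in column {col!r} at line(s) {rows}")
    return vals.to_numpy(dtype=float)


def read_titration(
    path,
    kind: str,
    fixed_totals: dict[str, float] | None = None,
    units: str = "M",
    temperature: float = 298.15,
) -> TitrationSeries:
    """Load one titration from CSV.

    ``direct``/``ida`` files need columns ``varied_total_M, signal``;
    ``ph`` files need ``pH, signal``.  Rows must already be sorted on the
    varied axis (strictly increasing); the offending line number is
    reported otherwise.
    """
    if units not in _UNIT_SCALE:
        raise ValidationError(f"units must be one of {sorted(_UNIT_SCALE)}")
    df = _read_csv(path)
    col = _PH_COL if kind == "ph" else _CONC_COL
    varied = _numeric(df, col, path)
    if kind != "ph":
        varied = varied * _UNIT_SCALE[units]
    signal = _numeric(df, _SIGNAL_COL, path)
    steps = np.diff(varied)
    if np.any(steps <= 0):
        line = int(np.argmax(steps <= 0)) + 3  # header + 1-based + next row
        raise ValidationError(
            f"{path}: column {col!r} must be strictly increasing (violated at line {line})"
        )
    return TitrationSeries(
        varied=varied,
        signal=signal,
        kind=kind,
        fixed_totals=dict(fixed_totals or {}),
        temperature=temperature,
    )


def write_titration(series: TitrationSeries, path) -> None:
    """Write a titration back to the CSV dialect ``read_titration`` accepts."""
    col = _PH_COL if series.kind == "ph" else _CONC_COL
    pd.DataFrame({col: series.varied, _SIGNAL_COL: series.signal}).to_csv(
        path, index=False
    )


def write_meta(series_or_dict, path) -> None:
    """Write ground-truth/config metadata as a JSON sidecar."""
    meta = series_or_dict if isinstance(series_or_dict, dict) else series_or_dict.meta

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(meta, indent=2, default=default) + "\n")


def read_grad_series(path, label: str = "") -> GradSeries:
    """Load an absorbance / integrated-emission table."""
    df = _read_csv(path)
    return GradSeries(
        absorbance=_numeric(df, "absorbance", path),
        integrated_emission=_numeric(df, "integrated_emission", path),
        label=label or Path(path).stem,
    )


def read_histogram(path, role: str = "decay") -> DecayHistogram:
    """Load a TCSPC histogram (columns ``time_ns, counts``)."""
    df = _read_csv(path)
    return DecayHistogram(
        time=_numeric(df, "time_ns", path),
        counts=_numeric(df, "counts", path),
        role=role,
    )


def read_thermo_table(path) -> pd.DataFrame:
    """Load a thermodynamics table (dH, minus_TdS, dG in kcal/mol; k_bind L/mol).

    Missing cells are allowed: each row only needs two derivable sources.
    """
    df = _read_csv(path)
    for col in ("dH", "minus_TdS", "dG", "k_bind"):
        if col not in df.columns:
            df[col] = np.nan
    if "temperature" not in df.columns:
        df["temperature"] = 298.15
    if "label" not in df.columns:
        df["label"] = [f"row{i}" for i in range(len(df))]
    return df
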