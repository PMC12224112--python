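"""Thermodynamic conversions, the IDA applicability window, and calibration.

Conversions use DeltaG = -RT ln K with R = 1.9872e-3 kcal mol^-1 K^-1 and
an implicit 1 mol/L standard state.  Calorimetric (ITC) quantities are
conventionally converted at 298.15 K; binding constants derived from
molecular-dynamics free energies at 300 K (the simulation temperature).

An indicator displacement assay can quantify analytes whose host
affinity lies within the window

    log K_HI - 2  <=  log K_HG  <=  log K_HI + 1

around the indicator's own constant K_HI — three decades wide for any
indicator.

Calibration is ordinary least squares of signal vs concentration; the
limit of detection follows the 3*sigma/|slope| convention (3.3*sigma
available), with sigma the residual standard deviation of the line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .errors import DegenerateDataError, RangeError, ValidationError

__all__ = [
    "R_KCAL",
    "ThermoRecord",
    "ConsistencyReport",
    "IdaWindow",
    "Calibration",
    "gibbs_from_k",
    "k_from_gibbs",
    "check_consistency",
    "ida_window",
    "fit_calibration",
    "lod",
]

R_KCAL = 1.9872e-3  # kcal mol^-1 K^-1
_FLAG_TOL = 0.1  # kcal/mol


def gibbs_from_k(k_bind: float, temperature: float = 298.15) -> float:
    """Standard binding free energy -RT ln K in kcal/mol."""
    if k_bind <= 0:
        raise ValidationError("k_bind must be positive (L/mol)")
    if temperature <= 0:
        raise ValidationError("temperature must be positive (K)")
    return -R_KCAL * temperature * math.log(k_bind)


def k_from_gibbs(dg: float, temperature: float = 298.15) -> float:
    """Association constant exp(-dG/RT); exact inverse of gibbs_from_k."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive (K)")
    x = -dg / (R_KCAL * temperature)
    if abs(x) > 700.0:
        raise RangeError("|dG|/RT too large; exp would overflow")
    return math.exp(x)


@dataclass
class ThermoRecord:
    """One complex's thermodynamics: dH, -TdS, dG (kcal/mol), K (L/mol)."""

    dH: float | None = None
    minus_TdS: float | None = None
    dG: float | None = None
    k_bind: float | None = None
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")
        if self.k_bind is not None and self.k_bind <= 0:
            raise ValidationError("k_bind must be positive (L/mol)")


@dataclass(frozen=True)
class ConsistencyReport:
    record: ThermoRecord
    dG_from_hs: float | None  # dH + (-TdS)
    dG_from_k: float | None  # -RT ln K
    k_from_dG: float | None
    discrepancies: dict[str, float]
    consistent: bool
    enthalpy_driven: bool | None
    flags: tuple[str, ...]


def check_consistency(rec: ThermoRecord) -> ConsistencyReport:
    """Cross-check dG = dH + (-TdS) and dG = -RT ln K at 0.1 kcal/mol.

    The binding is classified enthalpy-driven when |dH| > |TdS|.
    """
    have_hs = rec.dH is not None and rec.minus_TdS is not None
    sources = sum([have_hs, rec.dG is not None, rec.k_bind is not None])
    if sources < 2:
        raise ValidationError(
            "need at least two of {dH + (-TdS), dG, k_bind} to cross-check"
        )
    dg_hs = rec.dH + rec.minus_TdS if have_hs else None
    dg_k = gibbs_from_k(rec.k_bind, rec.temperature) if rec.k_bind is not None else None
    k_dg = k_from_gibbs(rec.dG, rec.temperature) if rec.dG is not None else None
    disc: dict[str, float] = {}
    flags: list[str] = []
    pairs = {
        "dG_vs_dH_plus_minusTdS": (rec.dG, dg_hs),
        "dG_vs_minus_RT_lnK": (rec.dG, dg_k),
        "dH_plus_minusTdS_vs_minus_RT_lnK": (dg_hs, dg_k),
    }
    for name, (a, b) in pairs.items():
        if a is not None and b is not None:
            d = a - b
            disc[name] = d
            if abs(d) > _FLAG_TOL:
                flags.append(f"{name}: |{d:.3f}| kcal/mol > {_FLAG_TOL}")
    enthalpy_driven = abs(rec.dH) > abs(rec.minus_TdS) if have_hs else None
    return ConsistencyReport(
        record=rec,
        dG_from_hs=dg_hs,
        dG_from_k=dg_k,
        k_from_dG=k_dg,
        discrepancies=disc,
        consistent=not flags,
        enthalpy_driven=enthalpy_driven,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class IdaWindow:
    """log10 K_HG window an IDA built on a given indicator can resolve."""

    log_lower: float
    log_upper: float

    @property
    def width(self) -> float:
        return self.log_upper - self.log_lower


def ida_window(k_indicator: float) -> IdaWindow:
    """Three-decade analyte window around the indicator's constant."""
    if k_indicator <= 0:
        raise ValidationError("indicator constant must be positive")
    logk = math.log10(k_indicator)
    return IdaWindow(log_lower=logk - 2.0, log_upper=logk + 1.0)


@dataclass(frozen=True)
class Calibration:
    """Straight-line calibration: signal = slope * conc + intercept."""

    slope: float
    intercept: float
    sigma: float  # residual standard deviation, signal units
    range_low: float
    range_high: float
    n_points: int


def fit_calibration(conc, signal) -> Calibration:
    """OLS calibration line; sigma = sqrt(SSR / (n - 2)).

    With absorbance as the signal and a 1 cm path this doubles as a
    Beer-Lambert molar-absorptivity (epsilon) extraction.
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if conc.ndim != 1 or conc.shape != signal.shape:
        raise ValidationError("conc and signal must be equal-length vectors")
    if conc.size < 4:
        raise ValidationError("calibration needs at least 4 points")
    if np.ptp(conc) == 0:
        raise DegenerateDataError("all concentrations identical; slope undefined")
    fit = linregress(conc, signal)
    resid = signal - (fit.slope * conc + fit.intercept)
    sigma = float(np.sqrt(np.sum(resid**2) / (conc.size - 2)))
    return Calibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        sigma=sigma,
        range_low=float(conc.min()),
        range_high=float(conc.max()),
        n_points=int(conc.size),
    )


def lod(cal: Calibration, factor: float = 3.0) -> float:
    """Limit of detection, ``factor * sigma / |slope|`` (mol/L)."""
    if cal.slope == 0:
        raise ValidationError("calibration slope is zero; LOD undefined")
    if factor <= 0:
        raise ValidationError("LOD factor must be positive")
    return factor * cal.sigma / abs(cal.slope)
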