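"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator mirrors one experiment the fitters consume: direct and
competitive fluorescence titrations, sigmoidal pH titrations, TCSPC
decay/IRF histogram pairs, and straight-line calibrations.  Every
generator takes an explicit seed (one named numpy generator per call, no
global state) and records its ground-truth parameters in the produced
object's ``meta``, so noiseless output is exactly invertible by the
corresponding fitter.

``replica_design`` bundles the concentration schedules and published
constants of the study's own experiments (the two direct titrations of
the quinolinone probes DQ1/DQ2 against the CB7 macrocycle, the methyl
viologen displacement assay, and its linear-range calibration) so those
experiments can be re-simulated with one call.  Replicated-composition
injection schedules are used for the titrations: points cluster at the
compositions that carry the most information about K (locally D-optimal
placement), which is how one would design these assays for constant
estimation rather than for curve display.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError
from .photophysics import DecayHistogram
from .titration import TitrationSeries, predict_direct, predict_ida, predict_pka

__all__ = [
    "NoiseSpec",
    "gen_direct_titration",
    "gen_ida_titration",
    "gen_ph_titration",
    "gen_decay",
    "gen_calibration",
    "replica_design",
]

_NOISE_MODELS = ("none", "gaussian_relative", "gaussian_absolute", "poisson")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model applied to a generated signal.

    ``gaussian_relative`` scale is a fraction of each point's value (the
    default 0.02 emulates ~2% photometric repeatability);
    ``gaussian_absolute`` scale is in signal units; ``poisson`` treats the
    signal as expected counts.
    """

    model: str = "gaussian_relative"
    scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _NOISE_MODELS:
            raise ValidationError(f"noise model must be one of {_NOISE_MODELS}")
        if self.scale < 0:
            raise ValidationError("noise scale must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.model == "none" or self.scale == 0 and self.model != "poisson":
            return values.copy()
        rng = np.random.default_rng(self.seed)
        if self.model == "gaussian_relative":
            return values * (1.0 + self.scale * rng.standard_normal(values.shape))
        if self.model == "gaussian_absolute":
            return values + self.scale * rng.standard_normal(values.shape)
        if np.any(values < 0):
            raise ValidationError("poisson noise requires non-negative expected counts")
        return rng.poisson(values).astype(float)


NONE = NoiseSpec(model="none", scale=0.0)


def gen_direct_titration(
    k_bind: float,
    reporter_total: float,
    host_grid,
    i_free: float,
    i_bound: float,
    noise: NoiseSpec = NONE,
) -> TitrationSeries:
    """Simulate a direct 1:1 titration (reporter fixed, host varied)."""
    series = TitrationSeries(
        varied=np.asarray(host_grid, dtype=float),
        signal=np.zeros(len(host_grid)),
        kind="direct",
        fixed_totals={"reporter": reporter_total},
    )
    clean = predict_direct(series, k_bind, i_free, i_bound)
    series.signal = noise.apply(clean)
    series.meta = {
        "truth": {"k_bind": k_bind, "i_free": i_free, "i_bound": i_bound},
        "noise": asdict(noise),
    }
    return series


def gen_ida_titration(
    k1: float,
    k2: float,
    host_total: float,
    indicator_total: float,
    guest_grid,
    i_complexed: float,
    i_free_ind: float,
    noise: NoiseSpec = NONE,
) -> TitrationSeries:
    """Simulate an indicator-displacement titration (guest varied).

    With a turn-on indicator (i_complexed > i_free_ind) and no noise the
    signal is non-increasing in guest total.
    """
    series = TitrationSeries(
        varied=np.asarray(guest_grid, dtype=float),
        signal=np.zeros(len(guest_grid)),
        kind="ida",
        fixed_totals={"host": host_total, "indicator": indicator_total},
    )
    clean = predict_ida(series, k1, k2, i_complexed, i_free_ind)
    series.signal = noise.apply(clean)
    series.meta = {
        "truth": {
            "k1": k1,
            "k2": k2,
            "i_complexed": i_complexed,
            "i_free_ind": i_free_ind,
        },
        "noise": asdict(noise),
    }
    return series


def gen_ph_titration(
    pka: float,
    a_acid: float,
    a_base: float,
    ph_grid,
    noise: NoiseSpec = NONE,
) -> TitrationSeries:
    """Simulate a single-protonation pH titration."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    series = TitrationSeries(
        varied=ph_grid,
        signal=np.zeros(ph_grid.size),
        kind="ph",
        fixed_totals={},
    )
    clean = predict_pka(ph_grid, pka, a_acid, a_base)
    series.signal = noise.apply(clean)
    series.meta = {
        "truth": {"pka": pka, "a_acid": a_acid, "a_base": a_base},
        "noise": asdict(noise),
    }
    if not (ph_grid[0] <= pka - 1.0 and pka + 1.0 <= ph_grid[-1]):
        series.meta["warning"] = "pH grid does not span pka +/- 1; fit may be unreliable"
    return series


def gen_decay(
    taus,
    fractions_percent,
    irf_sigma_ns: float,
    total_counts: int = 10_000,
    bin_width_ns: float = 0.02,
    window_ns: float = 25.0,
    seed: int = 0,
    irf_center_ns: float = 1.0,
    irf_counts_factor: int = 10,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Simulate a TCSPC decay/IRF histogram pair by photon sampling.

    Photon arrival times are drawn as an exponential mixture: component i
    emits ``fractions_percent[i]`` percent of the detected photons (the
    intensity fraction reported by the decay fitter), plus a Gaussian
    instrument response centered at ``irf_center_ns``.  Arrivals outside
    the acquisition window are redrawn, so the decay histogram holds
    exactly ``total_counts`` photons.  Poisson statistics are inherent in
    the per-bin counts.  The IRF histogram is acquired at
    ``irf_counts_factor`` times the decay counts.
    """
    taus = np.asarray(taus, dtype=float)
    fr = np.asarray(fractions_percent, dtype=float)
    if taus.ndim != 1 or taus.shape != fr.shape or taus.size == 0:
        raise ValidationError("taus and fractions_percent must be equal-length vectors")
    if np.any(taus <= 0):
        raise ValidationError("lifetimes must be positive")
    if np.any(fr < 0) or abs(fr.sum() - 100.0) > 1e-6:
        raise ValidationError("amplitude fractions must be non-negative and sum to 100")
    if total_counts < 1_000:
        raise ValidationError("need at least 1000 counts for a usable histogram")
    if irf_sigma_ns < 0 or bin_width_ns <= 0 or window_ns <= bin_width_ns:
        raise ValidationError("invalid histogram geometry")
    rng = np.random.default_rng(seed)
    p = fr / fr.sum()

    def sample_arrivals(n: int, with_decay: bool) -> np.ndarray:
        out = np.empty(0)
        while out.size < n:
            m = n - out.size
            t = rng.normal(irf_center_ns, irf_sigma_ns, m)
            if with_decay:
                comp = rng.choice(taus.size, size=m, p=p)
                t = t + rng.exponential(taus[comp])
            t = t[(t >= 0.0) & (t < window_ns)]
            out = np.concatenate([out, t])
        return out

    edges = np.arange(0.0, window_ns + bin_width_ns / 2, bin_width_ns)
    centers = edges[:-1] + bin_width_ns / 2
    decay_counts, _ = np.histogram(sample_arrivals(total_counts, True), bins=edges)
    irf_counts, _ = np.histogram(
        sample_arrivals(total_counts * irf_counts_factor, False), bins=edges
    )
    if irf_counts.sum() == 0:  # pragma: no cover - needs sigma ~ 0 and unlucky binning
        raise ValidationError("IRF histogram empty; widen the window")
    return (
        DecayHistogram(time=centers, counts=decay_counts, role="decay"),
        DecayHistogram(time=centers, counts=irf_counts, role="irf"),
    )


def gen_calibration(
    slope: float,
    intercept: float,
    sigma: float,
    conc_grid,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a straight-line calibration with Gaussian noise."""
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    conc = np.asarray(conc_grid, dtype=float)
    rng = np.random.default_rng(seed)
    signal = slope * conc + intercept + sigma * rng.standard_normal(conc.size)
    return conc, signal


# ---------------------------------------------------------------------------
# Replicas of the study's own experiment designs (concentrations in mol/L).
# Host grids place replicate-like injection clusters at the informative
# compositions (near the equivalence point and on the plateau); published
# constants serve as ground truth.  Intensity scales follow the measured
# quantum-yield enhancements (5.4-fold for DQ1, 18-fold for DQ2).
# ---------------------------------------------------------------------------

_DESIGNS: dict[str, dict] = {
    # DQ1 (1.6 uM) titrated with CB7 0-70 uM; K_b = 7.5e6 L/mol
    "direct_dq1": dict(
        kind="direct",
        k_bind=7.5e6,
        reporter_total=1.6e-6,
        host_grid=1e-6
        * np.array([0, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 30, 40, 50, 60, 65, 68, 69, 70]),
        i_free=100.0,
        i_bound=540.0,
    ),
    # DQ2 (1 uM) titrated with CB7 0-3 uM; K_b = 1.1e7 L/mol
    "direct_dq2": dict(
        kind="direct",
        k_bind=1.1e7,
        reporter_total=1.0e-6,
        host_grid=1e-6
        * np.array(
            [0, 0.80, 0.85, 0.90, 0.95, 1.00, 1.05, 1.10, 2.65, 2.70, 2.75, 2.80, 2.85, 2.90, 3.00]
        ),
        i_free=100.0,
        i_bound=1800.0,
    ),
    # methyl viologen displacing DQ2 from CB7; K2 = 1.88e7 L/mol
    "ida_mv": dict(
        kind="ida",
        k1=1.1e7,
        k2=1.88e7,
        host_total=1.0e-6,
        indicator_total=1.0e-6,
        guest_grid=1e-6
        * np.array(
            [0, 0.05, 0.10, 0.15, 1.80, 1.90, 2.00, 2.10, 2.20, 2.30, 2.40, 4.70, 4.80, 4.90, 5.00]
        ),
        i_complexed=1800.0,
        i_free_ind=100.0,
    ),
    # IDA linear range 0.5-3 uM with LOD 0.24 uM: sigma = LOD * |slope| / 3
    "calibration_mv": dict(
        kind="calibration",
        slope=-3.0e8,  # signal per mol/L (turn-on indicator displaced -> signal falls)
        intercept=1700.0,
        sigma=0.24e-6 * 3.0e8 / 3.0,
        conc_grid=np.linspace(0.5e-6, 3.0e-6, 8),
    ),
    # biexponential decay of the DQ2-CB7 complex
    "decay_dq2_cb7": dict(
        kind="decay",
        taus=(1.21, 3.56),
        fractions_percent=(13.68, 86.32),
        irf_sigma_ns=0.05,
        total_counts=10_000,
    ),
    # pH titrations: the probes show complexation-induced negative pKa
    # shifts; no numeric pKa is published, so plausible mid-acidic values
    # with a -1.5 shift are used as ground truth for round-trip studies.
    "ph_dq2": dict(
        kind="ph",
        pka=5.0,
        a_acid=0.65,
        a_base=0.20,
        ph_grid=np.linspace(2.0, 9.0, 15),
    ),
    "ph_dq2_cb7": dict(
        kind="ph",
        pka=3.5,
        a_acid=0.65,
        a_base=0.22,
        ph_grid=np.linspace(2.0, 9.0, 15),
    ),
}


def replica_design(name: str) -> dict:
    """Parameters (with ground truth) of one of the study's experiment designs."""
    try:
        d = dict(_DESIGNS[name])
    except KeyError:
        raise ValidationError(
            f"unknown design {name!r}; available: {sorted(_DESIGNS)}"
        ) from None
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.copy()
    return d
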