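"""Nonlinear least-squares fitting of fluorescence titrations.

Three experiment kinds are supported:

* ``direct`` — a fixed total of a fluorescent reporter (guest) titrated
  with host; the 1:1 binding constant and the two limiting intensities
  are estimated from  I_calc = X_HG I_HG + X_G I_G, where X are the mole
  fractions of the reporter obtained from the binary equilibrium.
* ``ida`` — indicator displacement: host + indicator fixed, a competing
  guest titrated in; the guest constant K2 is estimated with the
  indicator constant K1 held fixed, via the competitive equilibrium and
  I_calc = ([HI] I_HI + [I] I_I) / [I]_T.
* ``ph`` — spectrophotometric pKa: a single-protonation sigmoid
  A(pH) = (A_acid + A_base 10^(pH-pKa)) / (1 + 10^(pH-pKa)).

Binding constants are fitted internally as log10 K for conditioning and
reported in L/mol.  Multi-start (log-spaced K starts) guards against the
flat-in-log-K objective of poorly designed titrations; the best-so-far
cost after each start is recorded in ``trace`` and is non-increasing by
construction.  Uncertainty comes from a residual-resampling bootstrap
(:func:`bootstrap_ci`); the curvature intervals attached to fit results
are approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import CompetitiveMixture, bound_fraction, solve_competitive
from .errors import DegenerateDataError, FitError, ValidationError

__all__ = [
    "TitrationSeries",
    "DirectFitResult",
    "IdaFitResult",
    "PkaFitResult",
    "predict_direct",
    "predict_ida",
    "predict_pka",
    "fit_direct",
    "fit_ida",
    "fit_pka",
    "delta_pka",
    "bootstrap_ci",
]

_KINDS = ("direct", "ida", "ph")
_LOGK_BOUNDS = (0.0, 12.0)
_DEFAULT_STARTS = np.linspace(4.0, 9.0, 5)  # log10 K, L/mol


@dataclass
class TitrationSeries:
    """One titration: varied totals (or pH), fixed totals, observed signal."""

    varied: np.ndarray
    signal: np.ndarray
    kind: str
    fixed_totals: dict[str, float] = field(default_factory=dict)
    temperature: float = 298.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.varied = np.asarray(self.varied, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.varied.ndim != 1 or self.signal.shape != self.varied.shape:
            raise ValidationError("varied and signal must be 1-D vectors of equal length")
        if np.any(np.diff(self.varied) <= 0):
            raise ValidationError("varied axis must be strictly increasing")
        if self.kind != "ph" and np.any(self.varied < 0):
            raise ValidationError("concentrations must be non-negative (mol/L)")
        if any(v < 0 for v in self.fixed_totals.values()):
            raise ValidationError("fixed totals must be non-negative (mol/L)")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (K)")

    def __len__(self) -> int:
        return self.varied.size


def _require(series: TitrationSeries, kind: str, labels: Sequence[str]) -> None:
    if series.kind != kind:
        raise ValidationError(f"expected a {kind!r} series, got {series.kind!r}")
    for lab in labels:
        if lab not in series.fixed_totals:
            raise ValidationError(f"fixed_totals must contain {lab!r}")


def predict_direct(
    series: TitrationSeries, k_bind: float, i_free: float, i_bound: float
) -> np.ndarray:
    """Model intensities for a direct 1:1 titration (host varied).

    The reporter mole fractions satisfy X_HG + X_G = 1 exactly because
    both are computed from the same equilibrium speciation.
    """
    _require(series, "direct", ("reporter",))
    g_t = series.fixed_totals["reporter"]
    if g_t <= 0:
        raise ValidationError("reporter total must be positive")
    if k_bind < 0:
        raise ValidationError("k_bind must be non-negative")
    x_hg = bound_fraction(series.varied, g_t, k_bind)
    return x_hg * i_bound + (1.0 - x_hg) * i_free


def predict_ida(
    series: TitrationSeries,
    k1: float,
    k2: float,
    i_complexed: float,
    i_free_ind: float,
) -> np.ndarray:
    """Model intensities for an indicator-displacement titration (guest varied)."""
    _require(series, "ida", ("host", "indicator"))
    h_t = series.fixed_totals["host"]
    i_t = series.fixed_totals["indicator"]
    if i_t <= 0:
        raise ValidationError("indicator total must be positive")
    if k1 <= 0:
        raise ValidationError("k1 must be positive")
    out = np.empty(len(series))
    for i, g_t in enumerate(series.varied):
        st = solve_competitive(CompetitiveMixture(h_t, i_t, g_t, k1, k2))
        out[i] = (st.bound["HI"] * i_complexed + st.free["I"] * i_free_ind) / i_t
    return out


def predict_pka(ph: np.ndarray, pka: float, a_acid: float, a_base: float) -> np.ndarray:
    """Single-protonation sigmoid; equals (a_acid + a_base)/2 at pH = pKa."""
    r = np.power(10.0, np.asarray(ph, dtype=float) - pka)
    return (a_acid + a_base * r) / (1.0 + r)


@dataclass
class _FitResultBase:
    residual_norm: float
    ci: dict[str, tuple[float, float]]
    ci_method: str
    converged: bool
    trace: list[float]
    weighting: str


@dataclass
class DirectFitResult(_FitResultBase):
    k_bind: float = 0.0
    i_free: float = 0.0
    i_bound: float = 0.0

    @property
    def parameters(self) -> dict[str, float]:
        return {"k_bind": self.k_bind, "i_free": self.i_free, "i_bound": self.i_bound}


@dataclass
class IdaFitResult(_FitResultBase):
    k_guest: float = 0.0
    i_complexed_indicator: float = 0.0
    i_free_indicator: float = 0.0
    k1: float = 0.0  # held fixed during the fit; kept for bootstrap refits

    @property
    def parameters(self) -> dict[str, float]:
        return {
            "k_guest": self.k_guest,
            "i_complexed_indicator": self.i_complexed_indicator,
            "i_free_indicator": self.i_free_indicator,
        }


@dataclass
class PkaFitResult(_FitResultBase):
    pka: float = 0.0
    a_acid: float = 0.0
    a_base: float = 0.0
    reliable: bool = True

    @property
    def parameters(self) -> dict[str, float]:
        return {"pka": self.pka, "a_acid": self.a_acid, "a_base": self.a_base}


def _check_informative(signal: np.ndarray) -> None:
    span = float(np.ptp(signal))
    scale = float(np.max(np.abs(signal))) if signal.size else 0.0
    if span == 0.0 or span < 1e-9 * max(scale, 1e-300):
        raise DegenerateDataError("signal is (near-)constant; parameters not identifiable")


def _weights(signal: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(signal)
    if weighting == "relative":
        scale = np.max(np.abs(signal))
        return 1.0 / np.maximum(np.abs(signal), 1e-6 * max(scale, 1e-300))
    raise ValidationError(f"unknown weighting {weighting!r}; use 'none' or 'relative'")


_IRLS_ROUNDS = 2  # model-based reweighting passes after the initial fit


def _multistart_lsq(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[object, list[float]]:
    """Bounded least squares from several starts; lowest cost wins.

    Ties (within 1e-12 relative) are broken in favour of the start with the
    smaller first parameter (log10 K by convention).  The returned trace
    holds the best-so-far cost after each start and is non-increasing.
    """
    best = None
    best_cost = np.inf
    trace: list[float] = []
    for x0 in starts:
        try:
            res = least_squares(
                residual,
                np.clip(x0, lower, upper),
                bounds=(lower, upper),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost * (1.0 - 1e-12) or (
            abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300)
            and res.x[0] < best.x[0]
        ):
            best = res
        best_cost = min(best_cost, res.cost)
        trace.append(best_cost)
    if best is None:
        raise FitError("fit failed to converge from every start")
    return best, trace


def _irls_polish(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    best,
    lower: np.ndarray,
    upper: np.ndarray,
):
    """Re-derive relative weights from the fitted curve and refit.

    Weighting by the observed (noisy) signal slightly biases a
    relative-error fit; two reweighting passes with weights taken from
    the model curve remove that bias (standard iteratively reweighted
    least squares).
    """
    for _ in range(_IRLS_ROUNDS):
        mu = np.abs(predict(best.x))
        w = 1.0 / np.maximum(mu, 1e-6 * max(mu.max(), 1e-300))

        def residual(p: np.ndarray) -> np.ndarray:
            return (predict(p) - y) * w

        best = least_squares(
            residual, best.x, bounds=(lower, upper),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
        )
    return best


def _curvature_ci(res, n_obs: int, names: Sequence[str], log_first: bool) -> dict:
    """Approximate 95% intervals from the Jacobian at the optimum."""
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        sd = np.full(res.x.size, np.nan)
    ci = {}
    for j, name in enumerate(names):
        lo, hi = res.x[j] - 1.96 * sd[j], res.x[j] + 1.96 * sd[j]
        if j == 0 and log_first:
            lo, hi = 10.0**lo, 10.0**hi
        ci[name] = (float(lo), float(hi))
    return ci


def fit_direct(
    series: TitrationSeries,
    init: dict[str, float] | None = None,
    *,
    weighting: str = "none",
    starts: Sequence[float] | None = None,
) -> DirectFitResult:
    """Estimate (K_b, I_G, I_HG) from a direct titration.

    ``weighting='relative'`` minimizes relative residuals, appropriate
    when the noise is proportional to the signal (the synthetic
    generator's default noise model); the default is unweighted.
    """
    _require(series, "direct", ("reporter",))
    if len(series) < 5:
        raise ValidationError("need at least 5 titration points to fit")
    _check_informative(series.signal)
    w = _weights(series.signal, weighting)
    y = series.signal

    def residual(p: np.ndarray) -> np.ndarray:
        return (predict_direct(series, 10.0 ** p[0], p[1], p[2]) - y) * w

    logk_starts = np.asarray(starts if starts is not None else _DEFAULT_STARTS, float)
    i_free0 = float(y[0])
    i_bound0 = float(y[-1])
    if init is not None:
        start_list = [
            np.array(
                [
                    np.log10(init.get("k_bind", 10.0 ** logk_starts[0])),
                    init.get("i_free", i_free0),
                    init.get("i_bound", i_bound0),
                ]
            )
        ]
    else:
        start_list = [np.array([lk, i_free0, i_bound0]) for lk in logk_starts]
    lower = np.array([_LOGK_BOUNDS[0], -np.inf, -np.inf])
    upper = np.array([_LOGK_BOUNDS[1], np.inf, np.inf])
    best, trace = _multistart_lsq(residual, start_list, lower, upper)
    if weighting == "relative":
        best = _irls_polish(
            lambda p: predict_direct(series, 10.0 ** p[0], p[1], p[2]), y, best, lower, upper
        )
    ci = _curvature_ci(best, len(series), ("k_bind", "i_free", "i_bound"), True)
    return DirectFitResult(
        k_bind=float(10.0 ** best.x[0]),
        i_free=float(best.x[1]),
        i_bound=float(best.x[2]),
        residual_norm=float(2.0 * best.cost),
        ci=ci,
        ci_method="curvature (approximate)",
        converged=bool(best.success),
        trace=trace,
        weighting=weighting,
    )


def fit_ida(
    series: TitrationSeries,
    k1: float,
    init: dict[str, float] | None = None,
    *,
    weighting: str = "none",
    starts: Sequence[float] | None = None,
) -> IdaFitResult:
    """Estimate (K2, I_HI, I_I) with the indicator constant K1 held fixed.

    K1 comes from a prior direct titration of the indicator; fitting it
    jointly with K2 is deliberately not offered (two-step procedure).
    """
    _require(series, "ida", ("host", "indicator"))
    if k1 <= 0:
        raise ValidationError("k1 must be positive")
    if len(series) < 5:
        raise ValidationError("need at least 5 titration points to fit")
    _check_informative(series.signal)
    w = _weights(series.signal, weighting)
    y = series.signal

    def residual(p: np.ndarray) -> np.ndarray:
        return (predict_ida(series, k1, 10.0 ** p[0], p[1], p[2]) - y) * w

    logk_starts = np.asarray(starts if starts is not None else _DEFAULT_STARTS, float)
    ic0, if0 = float(y[0]), float(y[-1])
    if init is not None:
        start_list = [
            np.array(
                [
                    np.log10(init.get("k_guest", 10.0 ** logk_starts[0])),
                    init.get("i_complexed_indicator", ic0),
                    init.get("i_free_indicator", if0),
                ]
            )
        ]
    else:
        start_list = [np.array([lk, ic0, if0]) for lk in logk_starts]
    lower = np.array([_LOGK_BOUNDS[0], -np.inf, -np.inf])
    upper = np.array([_LOGK_BOUNDS[1], np.inf, np.inf])
    best, trace = _multistart_lsq(residual, start_list, lower, upper)
    if weighting == "relative":
        best = _irls_polish(
            lambda p: predict_ida(series, k1, 10.0 ** p[0], p[1], p[2]), y, best, lower, upper
        )
    if np.corrcoef(series.varied, y)[0, 1] > 0.5:
        warnings.warn(
            "signal increases upon guest addition; inconsistent with displacement "
            "of a turn-on indicator",
            stacklevel=2,
        )
    ci = _curvature_ci(
        best, len(series), ("k_guest", "i_complexed_indicator", "i_free_indicator"), True
    )
    return IdaFitResult(
        k_guest=float(10.0 ** best.x[0]),
        i_complexed_indicator=float(best.x[1]),
        i_free_indicator=float(best.x[2]),
        residual_norm=float(2.0 * best.cost),
        ci=ci,
        ci_method="curvature (approximate)",
        converged=bool(best.success),
        trace=trace,
        weighting=weighting,
        k1=float(k1),
    )


def fit_pka(series: TitrationSeries, init: dict[str, float] | None = None) -> PkaFitResult:
    """Estimate pKa and the two plateau signals from a pH titration.

    The fitted curve evaluated at the fitted pKa equals the mean of the
    fitted plateaus by construction of the sigmoid.  A fit is flagged
    unreliable when the sampled pH range spans < 2 units or the fitted
    pKa falls outside the sampled range by more than 1 unit.
    """
    if series.kind != "ph":
        raise ValidationError("expected a 'ph' series")
    if len(series) < 5:
        raise ValidationError("need at least 5 pH points to fit")
    _check_informative(series.signal)
    ph, y = series.varied, series.signal
    span = float(ph[-1] - ph[0])

    def residual(p: np.ndarray) -> np.ndarray:
        return predict_pka(ph, p[0], p[1], p[2]) - y

    if init is not None:
        start_list = [
            np.array(
                [
                    init.get("pka", float(np.median(ph))),
                    init.get("a_acid", float(y[0])),
                    init.get("a_base", float(y[-1])),
                ]
            )
        ]
    else:
        qs = np.quantile(ph, [0.25, 0.5, 0.75])
        start_list = [np.array([q, float(y[0]), float(y[-1])]) for q in qs]
    lower = np.array([ph[0] - 6.0, -np.inf, -np.inf])
    upper = np.array([ph[-1] + 6.0, np.inf, np.inf])
    best, trace = _multistart_lsq(residual, start_list, lower, upper)
    pka = float(best.x[0])
    reliable = bool(span >= 2.0 and (ph[0] - 1.0) <= pka <= (ph[-1] + 1.0))
    if not reliable:
        warnings.warn(
            "pKa fit flagged unreliable (narrow pH range or pKa outside sampled range)",
            stacklevel=2,
        )
    # non-sigmoidal data: the optimum explains no more variance than a constant
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0 and 2.0 * best.cost > 0.99 * sst:
        raise FitError("data show no sigmoidal pH dependence")
    ci = _curvature_ci(best, len(series), ("pka", "a_acid", "a_base"), False)
    return PkaFitResult(
        pka=pka,
        a_acid=float(best.x[1]),
        a_base=float(best.x[2]),
        residual_norm=float(2.0 * best.cost),
        ci=ci,
        ci_method="curvature (approximate)",
        converged=bool(best.success),
        trace=trace,
        weighting="none",
        reliable=reliable,
    )


def delta_pka(free: PkaFitResult, complexed: PkaFitResult) -> float:
    """Complexation-induced pKa shift: pKa(complex) - pKa(free probe).

    Negative values mean the host stabilizes the neutral (deprotonated)
    form of the guest.  Unreliable input fits propagate as a warning.
    """
    if not (free.converged and complexed.converged):
        raise ValidationError("both pKa fits must have converged")
    if not (free.reliable and complexed.reliable):
        warnings.warn("pKa shift computed from unreliable fit(s)", stacklevel=2)
    return complexed.pka - free.pka


def _model_spec(series: TitrationSeries, fit):
    """(predict(p), x0, bounds, names, log_first) for the fitted model."""
    if isinstance(fit, DirectFitResult):
        return (
            lambda p: predict_direct(series, 10.0 ** p[0], p[1], p[2]),
            np.array([np.log10(fit.k_bind), fit.i_free, fit.i_bound]),
            (np.array([_LOGK_BOUNDS[0], -np.inf, -np.inf]),
             np.array([_LOGK_BOUNDS[1], np.inf, np.inf])),
            ("k_bind", "i_free", "i_bound"),
            True,
        )
    if isinstance(fit, IdaFitResult):
        return (
            lambda p: predict_ida(series, fit.k1, 10.0 ** p[0], p[1], p[2]),
            np.array([np.log10(fit.k_guest), fit.i_complexed_indicator, fit.i_free_indicator]),
            (np.array([_LOGK_BOUNDS[0], -np.inf, -np.inf]),
             np.array([_LOGK_BOUNDS[1], np.inf, np.inf])),
            ("k_guest", "i_complexed_indicator", "i_free_indicator"),
            True,
        )
    if isinstance(fit, PkaFitResult):
        ph = series.varied
        return (
            lambda p: predict_pka(ph, p[0], p[1], p[2]),
            np.array([fit.pka, fit.a_acid, fit.a_base]),
            (np.array([ph[0] - 6.0, -np.inf, -np.inf]),
             np.array([ph[-1] + 6.0, np.inf, np.inf])),
            ("pka", "a_acid", "a_base"),
            False,
        )
    raise ValidationError(f"unsupported fit result type {type(fit).__name__}")


def _fitted_curve(series: TitrationSeries, fit) -> np.ndarray:
    if isinstance(fit, DirectFitResult):
        return predict_direct(series, fit.k_bind, fit.i_free, fit.i_bound)
    if isinstance(fit, IdaFitResult):
        return predict_ida(
            series, fit.k1, fit.k_guest, fit.i_complexed_indicator, fit.i_free_indicator
        )
    return predict_pka(series.varied, fit.pka, fit.a_acid, fit.a_base)


def bootstrap_ci(
    series: TitrationSeries,
    fit,
    n_resamples: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals.

    Residuals of the converged fit are resampled with replacement, added
    back to the fitted curve, and the model is refitted from the point
    estimate with the weights of the original fit held fixed (standard
    residual-bootstrap practice).  Deterministic given ``seed``.  If more
    than 20% of refits fail a warning is raised and the intervals use
    the refits that succeeded.
    """
    if n_resamples < 200:
        raise ValidationError("n_resamples must be at least 200")
    if not fit.converged:
        raise ValidationError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    curve = _fitted_curve(series, fit)
    resid = series.signal - curve
    n = len(series)
    predict, x0, (lower, upper), names, log_first = _model_spec(series, fit)
    w = _weights(curve, fit.weighting)
    draws: dict[str, list[float]] = {k: [] for k in fit.parameters}
    failures = 0
    for _ in range(n_resamples):
        y_star = curve + resid[rng.integers(0, n, n)]

        def residual(p: np.ndarray) -> np.ndarray:
            return (predict(p) - y_star) * w

        try:
            res = least_squares(
                residual, x0, bounds=(lower, upper),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500,
            )
            if not res.success:
                raise FitError("bootstrap refit did not converge")
        except (FitError, ValueError):
            failures += 1
            continue
        for j, name in enumerate(names):
            val = 10.0 ** res.x[j] if (j == 0 and log_first) else res.x[j]
            draws[name].append(float(val))
    if failures > 0.2 * n_resamples:
        warnings.warn(
            f"bootstrap refit failure rate {failures / n_resamples:.0%} exceeds 20%; "
            "intervals may be unreliable",
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    out = {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            out[k] = (np.nan, np.nan)
        else:
            out[k] = (
                float(np.quantile(arr, alpha)),
                float(np.quantile(arr, 1.0 - alpha)),
            )
    return out
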