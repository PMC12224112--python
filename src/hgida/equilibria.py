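"""Closed-form and numeric solvers for 1:1 and competitive host-guest equilibria.

Two chemistries are covered:

* binary  H + G <-> HG            with  K_b = [HG] / ([H][G])
* ternary H + I <-> HI,  H + G <-> HG   (an indicator I and a guest G
  competing for the same host), with stepwise association constants
  K1 = [HI]/([H][I]) and K2 = [HG]/([H][G]).

All concentrations are total or free molarities (mol/L); association
constants are in L/mol.  Only 1:1 complexes are modelled.

Every closed-form path is cross-checked (in the test suite and, for the
cubic, at run time when root selection is ambiguous) against
:func:`oracle_equilibrium`, a bracketed one-dimensional root finder on the
free-host mass balance, which is monotone and therefore has a unique root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InternalConsistencyError, ValidationError

__all__ = [
    "BinaryPair",
    "CompetitiveMixture",
    "SpeciesState",
    "solve_binary",
    "solve_competitive",
    "oracle_equilibrium",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryPair:
    """Totals and association constant for a single 1:1 equilibrium."""

    host_total: float
    guest_total: float
    k_bind: float

    def __post_init__(self) -> None:
        if self.host_total < 0 or self.guest_total < 0:
            raise ValidationError("totals must be non-negative (mol/L)")
        if self.k_bind < 0:
            raise ValidationError("association constant must be non-negative (L/mol)")


@dataclass(frozen=True)
class CompetitiveMixture:
    """Totals and constants for an indicator/guest competition for one host."""

    host_total: float
    indicator_total: float
    guest_total: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if min(self.host_total, self.indicator_total, self.guest_total) < 0:
            raise ValidationError("totals must be non-negative (mol/L)")
        if self.k1 <= 0:
            raise ValidationError("indicator association constant k1 must be > 0")
        if self.k2 < 0:
            raise ValidationError("guest association constant k2 must be >= 0")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium speciation: free and bound concentrations (mol/L).

    ``residual`` is the largest absolute mass-balance violation across all
    components; valid solver output keeps it below 1e-12 x max(total, 1 M).
    """

    free: dict[str, float]
    bound: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0

    def __getitem__(self, label: str) -> float:
        if label in self.free:
            return self.free[label]
        return self.bound[label]


def _stable_positive_root(a: float, b: float, c: float) -> float:
    """Positive root of a x^2 + b x + c = 0 with a > 0, c <= 0.

    Uses the q-formulation (q = -(b + sign(b) sqrt(disc)) / 2) so no
    catastrophic cancellation occurs when K * totals >> 1.
    """
    disc = b * b - 4.0 * a * c
    if disc < 0:  # pragma: no cover - impossible for a>0, c<=0
        raise InternalConsistencyError("negative discriminant in binding quadratic")
    sq = math.sqrt(disc)
    if b >= 0:
        q = -0.5 * (b + sq)
        # roots are q/a (negative) and c/q (non-negative since c<=0, q<0)
        return c / q if q != 0 else 0.0
    q = -0.5 * (b - sq)
    return q / a


def bound_fraction(host_totals: np.ndarray, guest_total: float, k_bind: float) -> np.ndarray:
    """Vectorized mole fraction of bound guest across a host-total grid.

    Same stable free-host quadratic as :func:`solve_binary`, evaluated
    elementwise; used by the titration model in hot loops (bootstrap).
    """
    h_t = np.asarray(host_totals, dtype=float)
    if k_bind < 0:
        raise ValidationError("association constant must be non-negative (L/mol)")
    if k_bind == 0.0 or guest_total == 0.0:
        return np.zeros_like(h_t)
    b = 1.0 + k_bind * (guest_total - h_t)
    disc = np.sqrt(b * b + 4.0 * k_bind * h_t)
    q = -0.5 * (b + np.where(b >= 0, disc, -disc))
    h = np.where(b >= 0, np.divide(-h_t, q, out=np.zeros_like(q), where=q != 0), q / k_bind)
    kh = k_bind * h
    return kh / (1.0 + kh)


def solve_binary(pair: BinaryPair) -> SpeciesState:
    """Speciation of the 1:1 equilibrium H + G <-> HG.

    Solved as a quadratic in *free host* h:

        K h^2 + (1 + K (G_T - H_T)) h - H_T = 0

    after which [G] = G_T / (1 + K h) and [HG] = K h [G] follow, so the
    association constant is reproduced exactly by construction even under
    strong saturation.  Equivalent to the textbook quadratic in [HG] (same
    physical root: 0 <= [HG] <= min(H_T, G_T)) but numerically stable in
    the free-species concentrations.
    """
    h_t, g_t, k = pair.host_total, pair.guest_total, pair.k_bind
    if k == 0.0 or h_t == 0.0 or g_t == 0.0:
        return SpeciesState(
            free={"H": h_t, "G": g_t}, bound={"HG": 0.0}, residual=0.0
        )
    h = _stable_positive_root(k, 1.0 + k * (g_t - h_t), -h_t)
    g = g_t / (1.0 + k * h)
    hg = k * h * g
    if not (0.0 <= hg <= min(h_t, g_t) * (1.0 + 1e-9)):  # pragma: no cover
        raise InternalConsistencyError("no admissible root for binary equilibrium")
    residual = max(abs(h + hg - h_t), abs(g + hg - g_t))
    return SpeciesState(free={"H": h, "G": g}, bound={"HG": hg}, residual=residual)


def _competitive_from_free_host(mix: CompetitiveMixture, h: float) -> SpeciesState:
    """Full speciation given free host; indicator/guest balances exact."""
    i_free = mix.indicator_total / (1.0 + mix.k1 * h)
    g_free = mix.guest_total / (1.0 + mix.k2 * h)
    hi = mix.k1 * h * i_free
    hg = mix.k2 * h * g_free
    residual = abs(h + hi + hg - mix.host_total)
    return SpeciesState(
        free={"H": h, "I": i_free, "G": g_free},
        bound={"HI": hi, "HG": hg},
        residual=residual,
    )


def _host_balance(mix: CompetitiveMixture, h: float) -> float:
    """f(h) = h + [HI](h) + [HG](h) - H_T; strictly increasing in h."""
    return (
        h
        + mix.k1 * h * mix.indicator_total / (1.0 + mix.k1 * h)
        + mix.k2 * h * mix.guest_total / (1.0 + mix.k2 * h)
        - mix.host_total
    )


def solve_competitive(mix: CompetitiveMixture) -> SpeciesState:
    """Speciation of the competitive system H + I <-> HI, H + G <-> HG.

    Eliminating free indicator and free guest with their mass balances
    turns the host balance into a cubic in free host h:

        K1 K2 h^3
        + [K1 + K2 + K1 K2 (I_T + G_T - H_T)] h^2
        + [1 + K1 (I_T - H_T) + K2 (G_T - H_T)] h
        - H_T = 0

    The unique root in [0, H_T] is taken (the host balance is monotone);
    it is located with the closed-form companion-matrix roots and polished
    by Newton steps.  If root selection is ever ambiguous the bracketed
    numeric oracle is used instead and a warning is logged.
    """
    h_t = mix.host_total
    if mix.guest_total == 0.0 or mix.k2 == 0.0:
        state = solve_binary(BinaryPair(h_t, mix.indicator_total, mix.k1))
        g_free = mix.guest_total
        return SpeciesState(
            free={"H": state.free["H"], "I": state.free["G"], "G": g_free},
            bound={"HI": state.bound["HG"], "HG": 0.0},
            residual=state.residual,
        )
    if h_t == 0.0:
        return SpeciesState(
            free={"H": 0.0, "I": mix.indicator_total, "G": mix.guest_total},
            bound={"HI": 0.0, "HG": 0.0},
            residual=0.0,
        )
    coeffs = [
        mix.k1 * mix.k2,
        mix.k1 + mix.k2 + mix.k1 * mix.k2 * (mix.indicator_total + mix.guest_total - h_t),
        1.0 + mix.k1 * (mix.indicator_total - h_t) + mix.k2 * (mix.guest_total - h_t),
        -h_t,
    ]
    roots = np.roots(coeffs)
    tol = 1e-9 * max(h_t, 1e-30)
    admissible = [
        float(r.real)
        for r in roots
        if abs(r.imag) <= 1e-8 * max(abs(r), 1.0) and -tol <= r.real <= h_t + tol
    ]
    if len(admissible) != 1:
        log.warning(
            "competitive cubic gave %d admissible roots; falling back to the "
            "numeric mass-balance oracle",
            len(admissible),
        )
        return oracle_equilibrium(mix)
    h = min(max(admissible[0], 0.0), h_t)
    # Newton polish: np.roots is only accurate to ~1e-10 relative.
    for _ in range(3):
        f = _host_balance(mix, h)
        df = (
            1.0
            + mix.k1 * mix.indicator_total / (1.0 + mix.k1 * h) ** 2
            + mix.k2 * mix.guest_total / (1.0 + mix.k2 * h) ** 2
        )
        h = min(max(h - f / df, 0.0), h_t)
    return _competitive_from_free_host(mix, h)


def oracle_equilibrium(system: BinaryPair | CompetitiveMixture) -> SpeciesState:
    """Brute-force speciation by bracketed root finding on free host.

    Free indicator and free guest are expressed analytically given free
    host, so the host mass balance is a strictly increasing scalar function
    on [0, H_T] with exactly one root.  Serves as the independent oracle
    for both closed-form solvers.
    """
    if isinstance(system, BinaryPair):
        if system.k_bind == 0.0:
            return SpeciesState(
                free={"H": system.host_total, "G": system.guest_total},
                bound={"HG": 0.0},
            )
        state = oracle_equilibrium(
            CompetitiveMixture(
                host_total=system.host_total,
                indicator_total=system.guest_total,
                guest_total=0.0,
                k1=system.k_bind,
                k2=0.0,
            )
        )
        return SpeciesState(
            free={"H": state.free["H"], "G": state.free["I"]},
            bound={"HG": state.bound["HI"]},
            residual=state.residual,
        )
    h_t = system.host_total
    if h_t == 0.0:
        return _competitive_from_free_host(system, 0.0)
    f0 = _host_balance(system, 0.0)
    f1 = _host_balance(system, h_t)
    if f0 > 0 or f1 < 0:  # pragma: no cover - monotone balance makes this impossible
        raise InternalConsistencyError("free-host bracket failure")
    if f1 == 0.0:
        return _competitive_from_free_host(system, h_t)
    h = brentq(lambda x: _host_balance(system, x), 0.0, h_t, xtol=1e-300, rtol=1e-15)
    # one Newton step squeezes the residual to machine precision
    df = (
        1.0
        + system.k1 * system.indicator_total / (1.0 + system.k1 * h) ** 2
        + system.k2 * system.guest_total / (1.0 + system.k2 * h) ** 2
    )
    h = min(max(h - _host_balance(system, h) / df, 0.0), h_t)
    return _competitive_from_free_host(system, h)
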