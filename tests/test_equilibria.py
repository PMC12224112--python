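"""Closed-form equilibrium solvers vs the numeric mass-balance oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgida.equilibria import (
    BinaryPair,
    CompetitiveMixture,
    oracle_equilibrium,
    solve_binary,
    solve_competitive,
)
from hgida.errors import ValidationError

CONC = st.floats(min_value=1e-9, max_value=1e-3)
LOGK = st.floats(min_value=0.0, max_value=9.0)


def test_binary_equal_totals_half_bound():
    # hand-solved quadratic: HG^2 - 5e-6 HG + 4e-12 = 0 -> HG = 1 uM
    s = solve_binary(BinaryPair(2e-6, 2e-6, 1e6))
    assert s.bound["HG"] == pytest.approx(1e-6, rel=1e-12)
    assert s.free["H"] == pytest.approx(1e-6, rel=1e-12)
    assert s.free["G"] == pytest.approx(1e-6, rel=1e-12)


def test_binary_no_host_trivial():
    s = solve_binary(BinaryPair(0.0, 3e-6, 1e7))
    assert s.bound["HG"] == 0.0
    assert s.free["G"] == 3e-6


def test_binary_strong_saturation_endpoint():
    # large host excess: nearly all guest bound (bisection oracle value)
    s = solve_binary(BinaryPair(70e-6, 1.6e-6, 7.5e6))
    o = oracle_equilibrium(BinaryPair(70e-6, 1.6e-6, 7.5e6))
    assert s.bound["HG"] / 1.6e-6 == pytest.approx(0.998, abs=5e-4)
    assert s.bound["HG"] == pytest.approx(o.bound["HG"], rel=1e-9)


def test_binary_reproduces_constant():
    s = solve_binary(BinaryPair(5e-6, 2e-6, 3.3e7))
    k = s.bound["HG"] / (s.free["H"] * s.free["G"])
    assert k == pytest.approx(3.3e7, rel=1e-9)


def test_binary_rejects_negative_inputs():
    with pytest.raises(ValidationError):
        BinaryPair(-1e-6, 1e-6, 1e6)
    with pytest.raises(ValidationError):
        BinaryPair(1e-6, 1e-6, -1.0)


def test_competitive_no_guest_equals_binary():
    m = CompetitiveMixture(2e-6, 1.5e-6, 0.0, 1.1e7, 1.88e7)
    b = solve_binary(BinaryPair(2e-6, 1.5e-6, 1.1e7))
    c = solve_competitive(m)
    assert c.bound["HI"] == pytest.approx(b.bound["HG"], rel=1e-12)
    assert c.free["H"] == pytest.approx(b.free["H"], rel=1e-12)


def test_competitive_symmetry():
    m = CompetitiveMixture(1e-6, 2e-6, 2e-6, 5e6, 5e6)
    s = solve_competitive(m)
    assert s.bound["HI"] == pytest.approx(s.bound["HG"], rel=1e-9)


def test_competitive_matches_oracle_reference_point():
    m = CompetitiveMixture(1e-6, 1e-6, 2e-6, 1.1e7, 1.88e7)
    s = solve_competitive(m)
    o = oracle_equilibrium(m)
    for lbl in ("HI", "HG"):
        assert s.bound[lbl] == pytest.approx(o.bound[lbl], rel=1e-9)
    for lbl in ("H", "I", "G"):
        assert s.free[lbl] == pytest.approx(o.free[lbl], rel=1e-9)
    # frozen golden value from the oracle at build time
    assert o.bound["HG"] == pytest.approx(7.216713099629474e-07, rel=1e-9)


def test_oracle_trivial_cases():
    z = oracle_equilibrium(CompetitiveMixture(0.0, 0.0, 0.0, 1.0, 0.0))
    assert all(v == 0.0 for v in {**z.free, **z.bound}.values())
    s = oracle_equilibrium(BinaryPair(1e-6, 1e-6, 0.0))
    assert s.bound["HG"] == 0.0 and s.free["H"] == 1e-6


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(ht=CONC, it=CONC, gt=CONC, lk1=LOGK, lk2=LOGK)
def test_mass_conservation_and_oracle_equivalence(ht, it, gt, lk1, lk2):
    """Per-component mass balance holds to 1e-12 x total and the closed-form
    cubic agrees with the bracketed oracle to 1e-9 relative."""
    m = CompetitiveMixture(ht, it, gt, 10**lk1, 10**lk2)
    s = solve_competitive(m)
    o = oracle_equilibrium(m)
    assert s.free["H"] + s.bound["HI"] + s.bound["HG"] == pytest.approx(
        ht, abs=1e-12 * max(ht, 1.0)
    )
    assert s.free["I"] + s.bound["HI"] == pytest.approx(it, abs=1e-12 * max(it, 1.0))
    assert s.free["G"] + s.bound["HG"] == pytest.approx(gt, abs=1e-12 * max(gt, 1.0))
    scale = max(ht, it, gt)
    for lbl in ("HI", "HG"):
        assert s.bound[lbl] == pytest.approx(o.bound[lbl], rel=1e-9, abs=1e-9 * scale)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(ht=CONC, gt=CONC, lk=LOGK)
def test_binary_agrees_with_oracle(ht, gt, lk):
    p = BinaryPair(ht, gt, 10**lk)
    s, o = solve_binary(p), oracle_equilibrium(p)
    assert s.bound["HG"] == pytest.approx(o.bound["HG"], rel=1e-9, abs=1e-9 * max(ht, gt))


def test_bound_indicator_monotone_in_guest_and_constants():
    """Bound indicator falls with more competitor or stronger k2, rises
    with stronger k1 or more host."""
    base = dict(host_total=1e-6, indicator_total=1e-6, k1=1e7)
    hi = [
        solve_competitive(CompetitiveMixture(guest_total=g, k2=1e7, **base)).bound["HI"]
        for g in np.linspace(0, 10e-6, 12)
    ]
    assert all(a >= b - 1e-18 for a, b in zip(hi, hi[1:]))
    hi = [
        solve_competitive(CompetitiveMixture(guest_total=2e-6, k2=k2, **base)).bound["HI"]
        for k2 in np.geomspace(1e4, 1e9, 12)
    ]
    assert all(a >= b - 1e-18 for a, b in zip(hi, hi[1:]))
    hi = [
        solve_competitive(
            CompetitiveMixture(1e-6, 1e-6, 2e-6, k1, 1e7)
        ).bound["HI"]
        for k1 in np.geomspace(1e4, 1e9, 12)
    ]
    assert all(b >= a - 1e-18 for a, b in zip(hi, hi[1:]))
    hi = [
        solve_competitive(CompetitiveMixture(h, 1e-6, 2e-6, 1e7, 1e7)).bound["HI"]
        for h in np.linspace(0, 10e-6, 12)
    ]
    assert all(b >= a - 1e-18 for a, b in zip(hi, hi[1:]))


def test_continuity_at_vanishing_guest():
    b = solve_binary(BinaryPair(1e-6, 1e-6, 1e7)).bound["HG"]
    for g in (1e-12, 1e-15, 0.0):
        c = solve_competitive(CompetitiveMixture(1e-6, 1e-6, g, 1e7, 1e7))
        assert c.bound["HI"] == pytest.approx(b, rel=1e-4)
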