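"""Quantum-yield arithmetic and TCSPC reconvolution fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgida.errors import DegenerateDataError, ValidationError
from hgida.photophysics import (
    DecayHistogram,
    GradSeries,
    fit_decay,
    fold_change,
    gradient,
    quantum_yield,
)
from hgida.synthetic import gen_decay


class TestGradient:
    def test_exact_line(self):
        s = GradSeries(np.array([0.0, 0.01, 0.02]), np.array([0.0, 2.0, 4.0]))
        assert gradient(s) == pytest.approx(200.0)

    def test_zero_absorbance_variance_degenerate(self):
        s = GradSeries(np.array([0.01, 0.01, 0.01]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateDataError):
            gradient(s)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.0, 0.1, 20)
        y = 5.0 * x + 0.1 * rng.standard_normal(20)
        slope = gradient(GradSeries(x, y))
        se = 0.1 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slope - 5.0) <= 3 * se

    def test_high_absorbance_warns_inner_filter(self):
        with pytest.warns(UserWarning, match="inner-filter"):
            GradSeries(np.array([0.0, 0.1, 0.3]), np.array([0.0, 1.0, 2.0]))


class TestQuantumYield:
    def test_identity_case(self):
        assert quantum_yield(2.0, 2.0, 1.33, 1.33, 0.53).phi == pytest.approx(0.53)

    def test_above_unity_rejected(self):
        with pytest.raises(ValidationError, match="> 1"):
            quantum_yield(4.0, 2.0, 1.0, 1.0, 0.53)

    def test_reference_arithmetic(self):
        qy = quantum_yield(1.0, 2.0, 1.1, 1.0, 0.53)
        assert qy.phi == pytest.approx(0.53 * 0.5 * 1.21, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.1, 1.0),
        n=st.floats(1.0, 1.6),
        phi_s=st.floats(0.1, 0.9),
    )
    def test_scaling_linear_in_grad_quadratic_in_index(self, g, n, phi_s):
        base = quantum_yield(g, 2.0, n, 2.0, phi_s).phi
        doubled_grad = quantum_yield(2 * g, 2.0, n, 2.0, phi_s)
        assert doubled_grad.phi == pytest.approx(2 * base, rel=1e-9)
        scaled_n = quantum_yield(g, 2.0, 1.1 * n, 2.0, phi_s)
        assert scaled_n.phi == pytest.approx(1.21 * base, rel=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "phi_c,phi_f,expected",
        [(0.54, 0.03, 18.0), (0.049, 0.009, 5.444444444444445), (0.3, 0.3, 1.0)],
    )
    def test_ratios(self, phi_c, phi_f, expected):
        assert fold_change(phi_c, phi_f) == pytest.approx(expected, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(0.5, 0.0)


class TestFitDecay:
    def test_biexponential_recovery(self):
        """Median recovery over several seeded realizations stays within 10%
        on lifetimes and 5 pp on intensity fractions (the single-realization
        error on the short component is CRLB-limited to ~7% sd at 1e5 counts,
        so the median over seeds is the stable statement of the contract)."""
        # published lifetimes/fractions of the DQ2-CB7 complex as truth
        taus, fr = (1.21, 3.56), (13.68, 86.32)
        tau_errs, frac_errs = [], []
        for seed in range(5):
            decay, irf = gen_decay(taus, fr, 0.05, total_counts=100_000, seed=seed)
            fit = fit_decay(decay, irf, n_components=2)
            tau_errs.append(
                max(abs(t_fit / t_true - 1.0) for t_fit, t_true in zip(fit.taus, taus))
            )
            frac_errs.append(
                max(abs(f_fit - f_true) for f_fit, f_true in zip(fit.fractions, fr))
            )
            assert fit.chi2_reduced < 2.0
        assert np.median(tau_errs) <= 0.10
        assert np.median(frac_errs) <= 5.0

    def test_monoexponential_narrow_irf(self):
        decay, irf = gen_decay([2.0], [100.0], 0.005, total_counts=100_000, seed=7)
        fit = fit_decay(decay, irf, n_components=1)
        assert fit.taus[0] == pytest.approx(2.0, rel=0.02)

    def test_fractions_sum_to_100(self):
        decay, irf = gen_decay((0.5, 3.0), (40.0, 60.0), 0.05, total_counts=20_000, seed=3)
        fit = fit_decay(decay, irf, n_components=2)
        assert sum(fit.fractions) == pytest.approx(100.0, abs=1e-6)

    def test_pure_scatter_flagged(self):
        _, irf = gen_decay([2.0], [100.0], 0.05, total_counts=50_000, seed=9)
        scatter = DecayHistogram(irf.time, irf.counts, role="decay")
        with pytest.warns(UserWarning, match="scatter|chi-square"):
            fit = fit_decay(scatter, irf, n_components=1)
        assert fit.taus[0] < 5 * scatter.bin_width

    def test_invariant_to_irf_rescaling(self):
        decay, irf = gen_decay((1.21, 3.56), (13.68, 86.32), 0.05, total_counts=50_000, seed=5)
        fit1 = fit_decay(decay, irf, n_components=2)
        irf10 = DecayHistogram(irf.time, irf.counts * 10.0, role="irf")
        fit2 = fit_decay(decay, irf10, n_components=2)
        assert fit1.taus == pytest.approx(fit2.taus, rel=1e-6)

    def test_mismatched_axes_rejected(self):
        decay, irf = gen_decay([2.0], [100.0], 0.05, total_counts=10_000, seed=1)
        other = DecayHistogram(irf.time + 0.5, irf.counts, role="irf")
        with pytest.raises(ValidationError):
            fit_decay(decay, other)
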