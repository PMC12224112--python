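"""Titration prediction and fitting: recovery, degeneracy, bootstrap."""

import numpy as np
import pytest

from hgida.errors import DegenerateDataError, ValidationError
from hgida.synthetic import (
    NONE,
    NoiseSpec,
    gen_direct_titration,
    gen_ida_titration,
    gen_ph_titration,
)
from hgida.titration import (
    TitrationSeries,
    bootstrap_ci,
    delta_pka,
    fit_direct,
    fit_ida,
    fit_pka,
    predict_direct,
    predict_ida,
    predict_pka,
)

HOSTS = np.concatenate([[0.0], np.geomspace(0.1e-6, 50e-6, 14)])


def direct_series(signal=None, reporter=2e-6, hosts=HOSTS):
    return TitrationSeries(
        varied=hosts,
        signal=np.zeros(len(hosts)) if signal is None else signal,
        kind="direct",
        fixed_totals={"reporter": reporter},
    )


class TestPredictDirect:
    def test_no_binding_gives_free_intensity(self):
        y = predict_direct(direct_series(), 0.0, 7.0, 100.0)
        assert np.allclose(y, 7.0)

    def test_saturation_limit(self):
        s = direct_series(hosts=np.array([5e-3, 1e-2]), reporter=1e-6)
        y = predict_direct(s, 1e8, 0.0, 100.0)
        assert np.allclose(y, 100.0, rtol=1e-4)

    def test_half_bound_point(self):
        # 2 uM host + 2 uM reporter at K=1e6: mole fraction bound is 0.5
        s = direct_series(hosts=np.array([1e-6, 2e-6]), reporter=2e-6)
        y = predict_direct(s, 1e6, 0.0, 100.0)
        assert y[1] == pytest.approx(50.0, rel=1e-9)

    def test_missing_reporter_total_rejected(self):
        s = TitrationSeries(HOSTS, np.zeros(len(HOSTS)), "direct", {})
        with pytest.raises(ValidationError, match="reporter"):
            predict_direct(s, 1e6, 0.0, 1.0)


class TestPredictIda:
    def test_zero_guest_reduces_to_direct(self):
        guests = np.concatenate([[0.0], np.geomspace(1e-9, 5e-6, 9)])
        ida = TitrationSeries(
            guests, np.zeros(10), "ida", {"host": 1e-6, "indicator": 1e-6}
        )
        y = predict_ida(ida, 1e7, 1e7, 500.0, 10.0)
        direct = TitrationSeries(
            np.array([0.5e-6, 1e-6]), np.zeros(2), "direct", {"reporter": 1e-6}
        )
        y_dir = predict_direct(direct, 1e7, 10.0, 500.0)
        assert y[0] == pytest.approx(y_dir[1], rel=1e-12)

    def test_full_displacement_limit(self):
        ida = TitrationSeries(
            np.array([1e-3, 2e-3]), np.zeros(2), "ida", {"host": 1e-6, "indicator": 1e-6}
        )
        y = predict_ida(ida, 1e6, 1e12, 500.0, 10.0)
        assert np.allclose(y, 10.0, rtol=1e-3)


class TestFitDirect:
    def test_noiseless_recovery(self):
        series = gen_direct_titration(1e6, 2e-6, HOSTS, 10.0, 500.0, noise=NONE)
        fit = fit_direct(series)
        assert fit.k_bind == pytest.approx(1e6, rel=1e-4)
        assert fit.i_free == pytest.approx(10.0, rel=1e-4)
        assert fit.i_bound == pytest.approx(500.0, rel=1e-4)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_direct(direct_series(signal=np.full(len(HOSTS), 5.0)))

    def test_multistart_trace_non_increasing(self):
        series = gen_direct_titration(
            1e7, 1e-6, HOSTS, 10.0, 500.0,
            noise=NoiseSpec("gaussian_relative", 0.02, 3),
        )
        fit = fit_direct(series)
        assert all(a >= b for a, b in zip(fit.trace, fit.trace[1:]))

    @pytest.mark.parametrize("logk", [5, 6, 7, 8])
    def test_recovery_grid_one_percent_noise(self, logk):
        """Median relative error <= 2% at 1% noise across the affinity grid.

        Well-designed here means K * reporter ~ 1 with injection clusters at
        the informative compositions (zero, half-equivalence, plateau)."""
        k = 10.0**logk
        reporter = 1.0 / k
        hosts = (
            np.concatenate(
                [[0.0], np.linspace(0.45, 0.55, 7), np.linspace(36.0, 40.0, 7)]
            )
            * reporter
        )
        errs = []
        for rep in range(7):
            series = gen_direct_titration(
                k, reporter, hosts, 10.0, 500.0,
                noise=NoiseSpec("gaussian_relative", 0.01, 100 + rep),
            )
            errs.append(abs(fit_direct(series, weighting="relative").k_bind / k - 1.0))
        assert np.median(errs) <= 0.02


class TestFitIda:
    GUESTS = np.concatenate([[0.0], np.geomspace(0.05e-6, 8e-6, 14)])

    def test_noiseless_recovery(self):
        series = gen_ida_titration(
            1.1e7, 1e7, 1e-6, 1e-6, self.GUESTS, 500.0, 10.0, noise=NONE
        )
        fit = fit_ida(series, k1=1.1e7)
        assert fit.k_guest == pytest.approx(1e7, rel=1e-4)

    def test_invalid_k1_rejected(self):
        series = gen_ida_titration(
            1.1e7, 1e7, 1e-6, 1e-6, self.GUESTS, 500.0, 10.0, noise=NONE
        )
        with pytest.raises(ValidationError):
            fit_ida(series, k1=0.0)

    def test_inconsistent_displacement_direction_warns(self):
        clean = gen_ida_titration(
            1.1e7, 1e7, 1e-6, 1e-6, self.GUESTS, 500.0, 10.0, noise=NONE
        )
        flipped = TitrationSeries(
            clean.varied, clean.signal[::-1].copy(), "ida", clean.fixed_totals
        )
        with pytest.warns(UserWarning, match="displacement"):
            fit_ida(flipped, k1=1.1e7)


class TestFitPka:
    PH = np.linspace(2.0, 8.0, 15)

    def test_noiseless_recovery(self):
        series = gen_ph_titration(4.0, 0.9, 0.1, self.PH, noise=NONE)
        fit = fit_pka(series)
        assert fit.pka == pytest.approx(4.0, abs=1e-4)
        assert fit.reliable

    def test_constant_absorbance_degenerate(self):
        series = TitrationSeries(self.PH, np.full(15, 0.4), "ph")
        with pytest.raises(DegenerateDataError):
            fit_pka(series)

    def test_midpoint_equals_mean_of_plateaus(self):
        series = gen_ph_titration(
            5.0, 0.8, 0.2, self.PH, noise=NoiseSpec("gaussian_absolute", 0.01, 5)
        )
        fit = fit_pka(series)
        mid = predict_pka(np.array([fit.pka]), fit.pka, fit.a_acid, fit.a_base)[0]
        assert mid == pytest.approx((fit.a_acid + fit.a_base) / 2, rel=1e-12)

    def test_narrow_range_flagged_unreliable(self):
        ph = np.linspace(3.6, 4.4, 9)
        series = gen_ph_titration(4.0, 0.9, 0.1, ph, noise=NONE)
        with pytest.warns(UserWarning, match="unreliable"):
            fit = fit_pka(series)
        assert not fit.reliable


class TestDeltaPka:
    def test_shift_is_signed_difference(self):
        ph = np.linspace(2.0, 8.0, 15)
        free = fit_pka(gen_ph_titration(5.0, 0.9, 0.1, ph, noise=NONE))
        comp = fit_pka(gen_ph_titration(4.2, 0.9, 0.1, ph, noise=NONE))
        assert delta_pka(free, comp) == pytest.approx(-0.8, abs=1e-6)
        assert delta_pka(free, free) == 0.0

    def test_synthetic_shift_round_trip(self):
        ph = np.linspace(1.5, 8.0, 16)
        noise = NoiseSpec("gaussian_absolute", 0.005, 11)
        free = fit_pka(gen_ph_titration(5.0, 0.9, 0.1, ph, noise=noise))
        comp = fit_pka(
            gen_ph_titration(3.5, 0.9, 0.12, ph, noise=NoiseSpec("gaussian_absolute", 0.005, 12))
        )
        assert delta_pka(free, comp) == pytest.approx(-1.5, abs=0.1)


class TestBootstrap:
    def _fitted(self, seed=21):
        series = gen_direct_titration(
            1e6, 2e-6, HOSTS, 10.0, 500.0,
            noise=NoiseSpec("gaussian_relative", 0.02, seed),
        )
        return series, fit_direct(series)

    def test_seed_reproducible_bit_for_bit(self):
        series, fit = self._fitted()
        a = bootstrap_ci(series, fit, 200, seed=5)
        b = bootstrap_ci(series, fit, 200, seed=5)
        assert a == b

    def test_noiseless_intervals_collapse(self):
        series = gen_direct_titration(1e6, 2e-6, HOSTS, 10.0, 500.0, noise=NONE)
        fit = fit_direct(series)
        ci = bootstrap_ci(series, fit, 200, seed=5)
        lo, hi = ci["k_bind"]
        assert (hi - lo) / fit.k_bind < 1e-3

    def test_interval_covers_truth(self):
        series, fit = self._fitted()
        lo, hi = bootstrap_ci(series, fit, 300, seed=5)["k_bind"]
        assert lo < 1e6 < hi

    def test_coverage_simulation(self):
        """95% percentile intervals cover the generating constant in at
        least 90 of 100 outer replicates of the strong-binder design."""
        from hgida.synthetic import replica_design

        d = replica_design("direct_dq1")
        hits = 0
        for seed in range(100):
            series = gen_direct_titration(
                d["k_bind"], d["reporter_total"], d["host_grid"],
                d["i_free"], d["i_bound"],
                noise=NoiseSpec("gaussian_relative", 0.02, seed),
            )
            fit = fit_direct(series, weighting="relative")
            lo, hi = bootstrap_ci(series, fit, 500, seed=seed)["k_bind"]
            hits += lo <= d["k_bind"] <= hi
        assert hits >= 90
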