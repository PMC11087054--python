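"""Trace normalization, QC, fractional destaining, fits, residual tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmpools.destain import (ExpFit, NormalizedTrace, ROITrace,
                             baseline_slope, corrected_fractional_destain,
                             fit_double_exp, fit_single_exp, fold_decrease,
                             fractional_destain, normalize_trace,
                             population_summary, residual_report)
from fmpools.kinetics import closed_form_biexp

DT = 4.0  # s


def norm_trace(F, times=None, **kw):
    t = np.arange(len(F)) * DT if times is None else times
    return NormalizedTrace(times=np.asarray(t, float),
                           F=np.asarray(F, float), **kw)


def exp_trace(k, span_min=25.0):
    t = np.arange(0.0, span_min * 60, DT)
    return norm_trace(np.exp(-k * t / 60.0), times=t)


class TestNormalizeTrace:
    def test_constant_raw_equal_to_background_maps_to_zero(self):
        t = np.arange(0, 400, DT)
        raw = ROITrace(times=t, F_raw=np.full_like(t, 50.0), background=50.0)
        nt = normalize_trace(raw, (0, 100), (300, 400))
        np.testing.assert_allclose(nt.F, 0.0, atol=1e-12)

    def test_algebraic_recovery_of_the_underlying_exponential(self):
        # raw = bg * (0.2 + 0.8 e^{-kt}) with plateau 0.2 -> exactly e^{-kt}
        k = 0.1  # min^-1
        t = np.arange(0.0, 3600.0, DT)
        g = np.exp(-k * t / 60.0)
        bg = 75.0
        raw = ROITrace(times=t, F_raw=bg * (0.2 + 0.8 * g), background=bg)
        # baseline from the first frame (g = 1 there), plateau from the tail
        nt = normalize_trace(raw, (0.0, DT), (3600.0 - 40.0, 3600.0))
        plateau_true = 0.8 * g[-10:].mean()  # residual decay in the window
        np.testing.assert_allclose(
            nt.F, (0.8 * g - plateau_true) / (0.8 - plateau_true), atol=1e-9)

    def test_degenerate_normalization_raises(self):
        t = np.arange(0, 400, DT)
        raw = ROITrace(times=t, F_raw=np.linspace(50, 100, len(t)),
                       background=50.0)  # plateau brighter than baseline
        with pytest.raises(ValueError, match="degenerate"):
            normalize_trace(raw, (0, 40), (360, 400))


class TestBaselineSlope:
    def test_flat_trace_accepted_with_zero_loss(self):
        loss, ok = baseline_slope(norm_trace(np.ones(40)), (0, 160))
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_two_percent_per_minute_rejected(self):
        t = np.arange(0, 160, DT)
        loss, ok = baseline_slope(norm_trace(1 - 0.02 * t / 60, times=t),
                                  (0, 160))
        assert loss == pytest.approx(2.0, rel=1e-6)
        assert not ok

    def test_exactly_1p5_percent_is_accepted_boundary_inclusive(self):
        t = np.arange(0, 160, DT)
        loss, ok = baseline_slope(norm_trace(1 - 0.015 * t / 60, times=t),
                                  (0, 160))
        assert loss == pytest.approx(1.5, rel=1e-9)
        assert ok

    def test_window_shorter_than_three_frames_raises(self):
        with pytest.raises(ValueError):
            baseline_slope(norm_trace(np.ones(40)), (0, DT * 2))


class TestFractionalDestain:
    def test_flat_trace_has_zero_rate(self):
        est = fractional_destain(norm_trace(np.ones(400)), (0, 1.5))
        assert est.k_hat == pytest.approx(0.0, abs=1e-12)

    def test_windowed_estimate_on_known_exponential(self):
        # brute-force OLS oracle on e^{-0.1 t}, window [0, 1.5) at 4 s
        # sampling gives 0.0931336 (interval averaging biases below 0.1)
        est = fractional_destain(exp_trace(0.1), (0.0, 1.5))
        assert est.k_hat == pytest.approx(0.0931336, abs=1e-6)

    def test_estimate_is_scale_invariant(self):
        tr = exp_trace(0.08)
        a = fractional_destain(tr, (0, 1.5)).k_hat
        tr.F *= 37.5
        b = fractional_destain(tr, (0, 1.5)).k_hat
        assert a == pytest.approx(b, rel=1e-12)

    def test_consistency_estimator_approaches_instantaneous_rate(self):
        # dense sampling + shrinking window: k_hat -> k of the exponential
        k = 0.12
        t = np.arange(0.0, 60.0, 0.1)
        tr = norm_trace(np.exp(-k * t / 60.0), times=t)
        # interval averaging biases low by ~ k*T/2; the error shrinks with
        # the window and vanishes in the limit
        errs = []
        for win, tol in [((0, 1.5), 0.10), ((0, 0.5), 0.035), ((0, 0.1), 8e-3)]:
            khat = fractional_destain(tr, win).k_hat
            assert khat == pytest.approx(k, rel=tol)
            errs.append(abs(khat - k))
        assert errs == sorted(errs, reverse=True)

    def test_nonpositive_intensity_at_window_start_raises(self):
        tr = norm_trace(np.linspace(-0.1, -0.2, 100))
        with pytest.raises(ValueError, match="undefined"):
            fractional_destain(tr, (0, 1.5))

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            fractional_destain(exp_trace(0.1), (0.0, 0.1))


class TestCorrections:
    def test_zero_baseline_rate_is_identity(self):
        est = fractional_destain(exp_trace(0.1), (0, 1.5))
        cor = corrected_fractional_destain(est, 0.0)
        assert cor.k_hat == est.k_hat
        assert cor.corrected

    def test_subtraction_of_baseline_rate(self):
        est = fractional_destain(exp_trace(0.1), (0, 1.5))
        cor = corrected_fractional_destain(est, 0.0158)
        assert cor.k_hat == pytest.approx(est.k_hat - 0.0158)

    def test_fold_decrease_basics(self):
        assert fold_decrease(0.1, 0.1) == 1.0
        assert fold_decrease(0.087, 0.032) == pytest.approx(2.72, abs=0.005)
        with pytest.raises(ZeroDivisionError):
            fold_decrease(0.1, 0.0)

    def test_single_exponential_fold_decrease_near_unity(self):
        # for a single well-mixed pool at the slowly mobilized rate the
        # standard early/late windows give a ratio within 5% of 1
        tr = exp_trace(0.032)
        e = fractional_destain(tr, (0, 1.5))
        l = fractional_destain(tr, (21, 25))
        assert fold_decrease(e, l) == pytest.approx(1.0, abs=0.05)


class TestSingleExpFit:
    def test_exact_recovery_of_the_generating_rate(self):
        fit = fit_single_exp(exp_trace(0.05))
        assert fit.k == pytest.approx(0.05, abs=1e-8)
        assert fit.converged

    def test_rate_clipped_at_printed_upper_bound(self):
        fit = fit_single_exp(exp_trace(0.5, span_min=10.0))
        assert fit.k == pytest.approx(0.3, abs=1e-9)

    def test_biexponential_input_lands_between_the_two_rates(self):
        t = np.arange(0.0, 1500.0, DT)
        tr = norm_trace(closed_form_biexp(0.39, 0.18, 0.031, t / 60.0),
                        times=t)
        fit = fit_single_exp(tr)
        assert 0.031 < fit.k < 0.18
        # systematic residual structure: smoothed residuals wander far
        # beyond what i.i.d. noise would produce
        rep = residual_report(fit)
        assert np.max(np.abs(rep.smoothed)) > 0.01
        assert rep.p_value < 1e-6


class TestDoubleExpFit:
    def test_exact_recovery_of_generating_parameters(self):
        t = np.arange(0.0, 1500.0, DT)
        tr = norm_trace(closed_form_biexp(0.5, 0.2, 0.02, t / 60.0), times=t)
        fit = fit_double_exp(tr)
        assert fit.w_fast == pytest.approx(0.5, abs=1e-4)
        assert fit.k_fast == pytest.approx(0.2, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.02, rel=1e-4)
        assert fit.identifiable

    def test_rates_come_out_ordered(self):
        t = np.arange(0.0, 1500.0, DT)
        tr = norm_trace(closed_form_biexp(0.3, 0.25, 0.01, t / 60.0), times=t)
        fit = fit_double_exp(tr)
        assert fit.k_fast >= fit.k_slow

    def test_pure_single_exponential_flagged_non_identifiable(self):
        fit = fit_double_exp(exp_trace(0.05))
        assert not fit.identifiable


class TestResidualReport:
    def test_series_containing_0p3_residual_flags_outlier(self, rng):
        r = rng.normal(0, 0.01, 100)
        r[40] = 0.3
        rep = residual_report(ExpFit(kind="single", k=0.1, residuals=r))
        assert rep.outlier
        assert rep.max_abs_deviation == pytest.approx(0.3)

    def test_small_iid_noise_not_flagged(self, rng):
        r = rng.normal(0, 0.01, 100)
        rep = residual_report(ExpFit(kind="single", k=0.1, residuals=r))
        assert not rep.outlier

    def test_smoothing_window_is_five_frames_centered(self, rng):
        r = np.zeros(20)
        # sign-alternating background avoids a degenerate runs-test series
        r[::2], r[1::2] = 1e-9, -1e-9
        r[10] = 1.0
        rep = residual_report(ExpFit(kind="single", k=0.1, residuals=r))
        np.testing.assert_allclose(rep.smoothed[8:13], 0.2, atol=1e-8)
        np.testing.assert_allclose(rep.smoothed[7], 0.0, atol=1e-8)
        # edge frames average over the truncated window
        np.testing.assert_allclose(rep.smoothed[0], 0.0, atol=1e-8)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            residual_report(ExpFit(kind="single", k=0.1,
                                   residuals=np.zeros(5)))


class TestPopulationSummary:
    def test_single_prep_single_roi_summary_equals_trace(self):
        tr = exp_trace(0.05)
        s = population_summary([tr])
        np.testing.assert_allclose(s.mean, tr.F)
        np.testing.assert_allclose(s.sem, 0.0)
        assert s.n_preps == 1

    def test_mean_of_per_prep_medians(self):
        t = np.arange(0, 40, DT)
        a = norm_trace(np.full_like(t, 0.4, dtype=float), times=t,
                       prep_id="p1")
        b = norm_trace(np.full_like(t, 0.6, dtype=float), times=t,
                       prep_id="p2")
        s = population_summary([a, b])
        np.testing.assert_allclose(s.mean, 0.5)
        assert s.n_preps == 2

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            population_summary([])

    def test_mismatched_time_bases_raise(self):
        with pytest.raises(ValueError):
            population_summary([exp_trace(0.05), exp_trace(0.05, 10.0)])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(k=st.floats(0.005, 0.25), scale=st.floats(0.1, 100.0))
def test_windowed_estimator_independent_of_brightness(k, scale):
    t = np.arange(0.0, 300.0, DT)
    tr = NormalizedTrace(times=t, F=np.exp(-k * t / 60.0))
    a = fractional_destain(tr, (0, 1.5)).k_hat
    tr2 = NormalizedTrace(times=t, F=scale * np.exp(-k * t / 60.0))
    b = fractional_destain(tr2, (0, 1.5)).k_hat
    assert a == pytest.approx(b, rel=1e-9)
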