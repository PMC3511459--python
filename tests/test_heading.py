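"""Heading model family: conditional means, likelihood, fitting, selection."""

import numpy as np
import pytest

from circmove.circular import (
    kj_logpdf,
    vm_logpdf,
    wc_logpdf,
    wrap,
)
from circmove.heading import (
    Family,
    FixedAlpha,
    FixedLambda,
    FocalPoint,
    HeadingModelSpec,
    HeadingParams,
    Noise,
    fit_heading,
    heading_loglik,
    heading_residuals,
    select_model,
    step_mean,
)
from circmove.simulate import make_fixture, simulate_heading_series, simulate_trajectory
from circmove.trajectory import StepSeries, derive_steps

CAR_VM = HeadingModelSpec(Family.CAR, Noise.VM)
CAR_WC = HeadingModelSpec(Family.CAR, Noise.WC)
CAR_KJ = HeadingModelSpec(Family.CAR, Noise.KJ)
CRW_VM = HeadingModelSpec(Family.CRW, Noise.VM)


def _series(headings):
    h = np.asarray(headings, dtype=float)
    return StepSeries(1.0, h, np.ones(h.size))


class TestSpec:
    def test_free_parameter_counts(self):
        assert CRW_VM.n_free_params == 1
        assert HeadingModelSpec(Family.CRW, Noise.WC).n_free_params == 1
        assert CAR_VM.n_free_params == 3
        assert CAR_WC.n_free_params == 3
        assert CAR_KJ.n_free_params == 5

    def test_constraints_remove_one_parameter(self):
        assert HeadingModelSpec(Family.CAR, Noise.KJ,
                                FixedLambda(0.5)).n_free_params == 4
        assert HeadingModelSpec(Family.CAR, Noise.KJ,
                                FixedAlpha(0.5)).n_free_params == 4
        assert HeadingModelSpec(Family.CAR, Noise.KJ,
                                FocalPoint(0, 100)).n_free_params == 4
        assert HeadingModelSpec(Family.CAR, Noise.VM,
                                FocalPoint(0, 100)).n_free_params == 2

    def test_fixed_lambda_requires_kj(self):
        with pytest.raises(ValueError):
            HeadingModelSpec(Family.CAR, Noise.VM, FixedLambda(0.5))

    def test_alpha_constraints_require_car(self):
        with pytest.raises(ValueError):
            HeadingModelSpec(Family.CRW, Noise.VM, FixedAlpha(0.5))

    def test_missing_parameter_detected(self):
        with pytest.raises(ValueError, match="kappa"):
            HeadingParams(alpha=0.0, w=0.5).resolved(CAR_VM)


class TestStepMean:
    def test_crw_returns_previous(self):
        p = HeadingParams(kappa=6.0)
        assert step_mean(1.234, CRW_VM, p) == pytest.approx(1.234)

    def test_w0_returns_alpha(self):
        p = HeadingParams(alpha=0.8, w=0.0, kappa=6.0)
        assert step_mean(-2.0, CAR_VM, p) == pytest.approx(0.8)

    def test_focal_point_bearing(self):
        spec = HeadingModelSpec(Family.CAR, Noise.VM, FocalPoint(0.0, 100.0))
        p = HeadingParams(w=0.0, kappa=6.0)
        # from the origin the focal point lies due north
        assert step_mean(0.3, spec, p, current_location=(0.0, 0.0)) == \
            pytest.approx(np.pi / 2)

    def test_focal_point_needs_location(self):
        spec = HeadingModelSpec(Family.CAR, Noise.VM, FocalPoint(0.0, 100.0))
        p = HeadingParams(w=0.5, kappa=6.0)
        with pytest.raises(ValueError, match="location"):
            step_mean(0.3, spec, p)


class TestLoglik:
    def test_single_step_crw_vm(self):
        s = _series([0.2, 0.9])
        p = HeadingParams(kappa=3.0)
        ll = heading_loglik(s, CRW_VM, p)
        assert ll == pytest.approx(float(vm_logpdf(0.7, 0.0, 3.0)), abs=1e-12)

    def test_kj_r0_reduces_to_vm(self, wind_skewed_series):
        series, _ = wind_skewed_series
        base = dict(alpha=-0.3, w=0.6, kappa=5.0)
        ll_vm = heading_loglik(series, CAR_VM, HeadingParams(**base))
        ll_kj = heading_loglik(series, CAR_KJ,
                               HeadingParams(**base, r=0.0, lambda_=1.0))
        assert ll_kj == pytest.approx(ll_vm, abs=1e-9)

    def test_independent_per_step_summation(self, wind_skewed_series):
        series, sc = wind_skewed_series
        p = sc.heading_params.resolved(CAR_KJ)
        ll = heading_loglik(series, CAR_KJ, p)
        # brute-force loop, term by term
        th = series.headings
        total = 0.0
        for t in range(1, th.size):
            mu = step_mean(th[t - 1], CAR_KJ, p)
            nu = wrap(p.lambda_ - mu)
            total += float(kj_logpdf(th[t], mu, p.kappa, p.r, nu))
        assert ll == pytest.approx(total, abs=1e-9)

    def test_rotation_invariance(self, wind_skewed_series):
        series, sc = wind_skewed_series
        p = sc.heading_params.resolved(CAR_KJ)
        delta = 0.9
        rotated = _series(wrap(series.headings + delta))
        p_rot = HeadingParams(alpha=wrap(p.alpha + delta), w=p.w,
                              kappa=p.kappa, r=p.r,
                              lambda_=wrap(p.lambda_ + delta))
        assert heading_loglik(rotated, CAR_KJ, p_rot) == pytest.approx(
            heading_loglik(series, CAR_KJ, p), abs=1e-9)

    def test_wc_noise_matches_manual(self):
        s = _series([0.0, 0.5, -0.2, 0.1])
        p = HeadingParams(alpha=0.0, w=0.5, kappa=None, r=0.4)
        ll = heading_loglik(s, CAR_WC, p)
        th = s.headings
        manual = sum(
            float(wc_logpdf(wrap(th[t] - step_mean(th[t - 1], CAR_WC, p)), 0.0, 0.4))
            for t in range(1, 4))
        assert ll == pytest.approx(manual, abs=1e-12)


class TestFit:
    def test_refuses_short_series(self):
        with pytest.raises(ValueError, match="short"):
            fit_heading(_series(np.zeros(5)), CRW_VM)

    def test_aic_identity(self, oriented_series):
        series, _ = oriented_series
        fit = fit_heading(series, CAR_VM, n_starts=4, seed=0)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 3, abs=1e-10)

    def test_car_vm_parameter_recovery(self, oriented_series):
        series, sc = oriented_series
        fit = fit_heading(series, CAR_VM, n_starts=6, seed=0)
        t = sc.heading_params
        assert abs(wrap(fit.params.alpha - t.alpha)) < 0.15
        assert abs(fit.params.w - t.w) < 0.1
        assert abs(fit.params.kappa - t.kappa) < 1.0

    def test_crw_data_gives_w_near_one(self):
        spec = CRW_VM
        th = simulate_heading_series(spec, HeadingParams(kappa=6.0), 0.0,
                                     1999, 1, seed=3)[0]
        fit = fit_heading(_series(th), CAR_VM, n_starts=6, seed=1)
        assert abs(abs(fit.params.w) - 1.0) < 0.05

    def test_restart_at_optimum_does_not_decrease(self, oriented_series):
        series, _ = oriented_series
        fit = fit_heading(series, CAR_VM, n_starts=4, seed=0)
        refit = fit_heading(series, CAR_VM, n_starts=1, seed=1,
                            extra_starts=[fit.params])
        assert refit.loglik >= fit.loglik - 1e-6

    def test_deterministic_given_seed(self, oriented_series):
        series, _ = oriented_series
        f1 = fit_heading(series, CAR_VM, n_starts=4, seed=7)
        f2 = fit_heading(series, CAR_VM, n_starts=4, seed=7)
        assert f1.params == f2.params and f1.loglik == f2.loglik

    def test_alias_canonicalized(self, oriented_series):
        # (alpha, w) and (alpha+pi, 1/w) define the same map; the fit must
        # report the |w| <= 1 representative
        series, _ = oriented_series
        fit = fit_heading(series, CAR_VM, n_starts=6, seed=0)
        assert abs(fit.params.w) <= 1.0 + 1e-9


class TestNesting:
    def test_loglik_ordering(self, wind_skewed_series):
        series, _ = wind_skewed_series
        ranked = select_model(series, [CRW_VM, CAR_VM, CAR_KJ],
                              n_starts=4, seed=0)
        by_spec = {f.spec: f for f in ranked}
        tol = 1e-4
        assert by_spec[CAR_KJ].loglik >= by_spec[CAR_VM].loglik - tol
        assert by_spec[CAR_VM].loglik >= by_spec[CRW_VM].loglik - tol

    def test_selection_deterministic(self, oriented_series):
        series, _ = oriented_series
        r1 = select_model(series, [CRW_VM, CAR_VM], n_starts=3, seed=5)
        r2 = select_model(series, [CRW_VM, CAR_VM], n_starts=3, seed=5)
        assert [f.spec for f in r1] == [f.spec for f in r2]
        assert [f.aic for f in r1] == [f.aic for f in r2]

    def test_crw_truth_prefers_crw_on_average(self):
        wins = 0
        for s in range(8):
            th = simulate_heading_series(CRW_VM, HeadingParams(kappa=6.0),
                                         0.0, 999, 1, seed=50 + s)[0]
            ranked = select_model(_series(th), [CRW_VM, CAR_VM],
                                  n_starts=3, seed=s)
            wins += ranked[0].spec == CRW_VM
        assert wins >= 5


class TestResiduals:
    def test_crw_residuals_are_heading_differences(self):
        th = np.array([0.1, 0.5, -0.2, 0.4, 0.0])
        s = _series(th)
        fit = fit_heading(_series(np.tile(th, 4)), CRW_VM, n_starts=2, seed=0)
        res = heading_residuals(s, fit)
        np.testing.assert_allclose(res, wrap(np.diff(th)), atol=1e-12)

    def test_true_model_residuals_are_vm_white_noise(self, wind_skewed_series):
        from scipy import integrate, stats

        series, sc = wind_skewed_series
        from circmove.heading import FitResult
        p = sc.heading_params.resolved(CAR_KJ)
        fit = FitResult(CAR_KJ, p, 0.0, 0.0, series.n_steps)
        res = heading_residuals(series, fit)
        edges = np.linspace(-np.pi, np.pi, 13)
        obs, _ = np.histogram(res, edges)
        from circmove.circular import VonMisesParams, vm_pdf
        f = lambda y: vm_pdf(y, VonMisesParams(0.0, p.kappa))
        exp = np.array([integrate.quad(f, a, b)[0]
                        for a, b in zip(edges[:-1], edges[1:])]) * res.size
        keep = exp > 3
        stat = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        assert stats.chi2.sf(stat, keep.sum() - 1) > 0.01

    def test_kj_r0_residuals_match_vm_case(self, oriented_series):
        from circmove.heading import FitResult

        series, sc = oriented_series
        pv = sc.heading_params.resolved(CAR_VM)
        pk = HeadingParams(alpha=pv.alpha, w=pv.w, kappa=pv.kappa, r=0.0,
                           lambda_=0.7)
        rv = heading_residuals(series, FitResult(CAR_VM, pv, 0, 0, 0))
        rk = heading_residuals(series, FitResult(CAR_KJ, pk, 0, 0, 0))
        np.testing.assert_allclose(rv, rk, atol=1e-10)


class TestFocalPoint:
    def test_homing_fit_recovers_w(self):
        sc = make_fixture("homing", seed=5)
        series = derive_steps(simulate_trajectory(sc), 1.0)
        fit = fit_heading(series, sc.heading_spec, n_starts=4, seed=2,
                          extra_starts=[sc.heading_params])
        assert abs(fit.params.w - 0.8) < 0.25
        assert abs(fit.params.r - 0.2) < 0.15

    def test_loglik_requires_locations(self):
        spec = HeadingModelSpec(Family.CAR, Noise.VM, FocalPoint(0.0, 1e4))
        p = HeadingParams(w=0.5, kappa=6.0)
        s = _series(np.linspace(0, 1, 20))   # no fixes attached
        with pytest.raises(ValueError, match="locations"):
            heading_loglik(s, spec, p)
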