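import numpy as np
import pytest
from scipy.special import erf, factorial

import glvflux as g
from glvflux.memory import _TrajectoryCache


def ramp_weights():
    """Weights with p = t / N so that f = p * N = t exactly (test integrand)."""
    return g.TrophicWeights(p=lambda t, N, cumN: np.atleast_1d(t) / np.atleast_1d(N) * np.ones_like(N))


@pytest.fixture(scope="module")
def exp_trajectory():
    model = g.GLVModel(r=[1.0], A=[[0.0]])
    return g.integrate_glv(model, [1.0], 2.2, dt_out=0.002)


class TestGaussianMeasure:
    def test_flat_limit(self):
        m = g.gaussian_measure(0.0)
        s = np.linspace(0.0, 3.0, 7)
        np.testing.assert_array_equal(m.w(3.0, s), np.ones(7))
        np.testing.assert_array_equal(m.dw_dt(3.0, s), np.zeros(7))

    def test_point_values(self):
        m = g.gaussian_measure(1.0)
        assert m.w(1.0, np.array([0.0]))[0] == pytest.approx(np.exp(-1.0))
        assert m.dw_dt(1.0, np.array([0.0]))[0] == pytest.approx(-2.0 * np.exp(-1.0))
        assert m.w(5.0, np.array([5.0]))[0] == 1.0  # w(t, t) > 0

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            g.gaussian_measure(-0.5)

    def test_numeric_dwdt_fallback_matches_analytic(self):
        analytic = g.gaussian_measure(0.7)
        numeric = g.density_measure(analytic.w)
        assert numeric.dw_dt_numeric
        s = np.linspace(0.0, 2.0, 9)
        np.testing.assert_allclose(numeric.dw_dt(2.0, s), analytic.dw_dt(2.0, s),
                                   rtol=1e-6, atol=1e-8)


class TestTrophicFunctional:
    def test_dirac_pointwise_product(self):
        # stationary logistic at carrying capacity 3, p = 2 -> tau = 6
        model = g.GLVModel(r=[3.0], A=[[-1.0]])
        traj = g.integrate_glv(model, [3.0], 2.0, dt_out=0.01)
        tau = g.trophic_functional(traj, g.constant_weights(2.0, n=1), g.dirac_measure(), 1.5)
        assert tau[0] == pytest.approx(6.0, rel=1e-9)

    def test_flat_kernel_time_average_of_ramp(self, exp_trajectory):
        # f(s) = s, a = 0: tau(2) = (1/2) int_0^2 s ds = 1
        tau = g.trophic_functional(exp_trajectory, ramp_weights(), g.gaussian_measure(0.0), 2.0)
        assert tau[0] == pytest.approx(1.0, rel=1e-9)

    def test_gaussian_kernel_ramp_closed_form(self, exp_trajectory):
        # int_0^1 s exp(-(s-1)^2) ds = -1/2 + e^{-1}/2 + (sqrt(pi)/2) erf(1)
        exact = -0.5 + 0.5 * np.exp(-1.0) + 0.5 * np.sqrt(np.pi) * erf(1.0)
        tau = g.trophic_functional(exp_trajectory, ramp_weights(), g.gaussian_measure(1.0), 1.0)
        assert tau[0] == pytest.approx(exact, rel=1e-6)

    def test_t_zero_limit_definition(self, exp_trajectory):
        tau0 = g.trophic_functional(exp_trajectory, g.constant_weights(1.0, n=1),
                                    g.gaussian_measure(1.0), 0.0)
        assert tau0[0] == pytest.approx(1.0)  # p(0) N(0) w(0,0)
        tau_small = g.trophic_functional(exp_trajectory, g.constant_weights(1.0, n=1),
                                         g.gaussian_measure(1.0), 0.004)
        assert tau_small[0] == pytest.approx(tau0[0], rel=1e-2)

    def test_out_of_span_rejected(self, exp_trajectory):
        with pytest.raises(ValueError):
            g.trophic_functional(exp_trajectory, ramp_weights(), g.dirac_measure(), 99.0)

    def test_quadrature_refinement_second_order(self, exp_trajectory):
        # trapezoid error drops by ~4x when the step is halved
        exact = -0.5 + 0.5 * np.exp(-1.0) + 0.5 * np.sqrt(np.pi) * erf(1.0)
        meas = g.gaussian_measure(1.0)
        model = g.GLVModel(r=[1.0], A=[[0.0]])
        coarse_traj = g.integrate_glv(model, [1.0], 2.2, dt_out=0.05)
        err0 = abs(g.trophic_functional(coarse_traj, ramp_weights(), meas, 1.0)[0] - exact)
        err1 = abs(g.trophic_functional(coarse_traj, ramp_weights(), meas, 1.0, quad_refine=1)[0] - exact)
        assert err1 <= err0 / 3.0


class TestTrophicDerivative:
    def test_flat_kernel_ramp_constant_half(self, exp_trajectory):
        # tau(t) = t/2 for f = s, a = 0 -> d tau/dt = 1/2
        for t in (0.5, 1.0, 2.0):
            d = g.trophic_derivative(exp_trajectory, ramp_weights(), g.gaussian_measure(0.0), t)
            assert d[0] == pytest.approx(0.5, rel=1e-6)

    def test_dirac_unit_weights_reduce_to_glv_rhs(self):
        model = g.GLVModel(r=[1.0], A=[[-1.0]])
        traj = g.integrate_glv(model, [0.5], 4.0, dt_out=0.01)
        w = g.constant_weights(1.0, n=1)
        for t in (0.0, 1.0, 2.5):
            N = traj.N[np.argmin(np.abs(traj.t - t)), 0]
            d = g.trophic_derivative(traj, w, g.dirac_measure(), t)
            assert d[0] == pytest.approx(N * (1.0 - N), rel=1e-6)

    def test_matches_finite_difference_of_functional(self, wolf_rabbit_short):
        # the three-term formula against a central difference oracle
        w = g.constant_weights(1.0, n=2)
        meas = g.gaussian_measure(1.0)
        cache = _TrajectoryCache(wolf_rabbit_short, w, quad_refine=7)
        h = 1e-3
        for t in np.linspace(3.007, 12.007, 5):
            fd = (g.trophic_functional(wolf_rabbit_short, w, meas, t + h, _cache=cache)
                  - g.trophic_functional(wolf_rabbit_short, w, meas, t - h, _cache=cache)) / (2 * h)
            an = g.trophic_derivative(wolf_rabbit_short, w, meas, t, _cache=cache)
            assert np.max(np.abs(fd - an)) <= 1e-4 * np.max(np.abs(an))

    def test_density_derivative_requires_positive_t(self, exp_trajectory):
        with pytest.raises(ValueError):
            g.trophic_derivative(exp_trajectory, ramp_weights(), g.gaussian_measure(1.0), 0.0)


class TestTrophicSeries:
    def test_dirac_series_is_pointwise_product(self, wolf_rabbit_short):
        w = g.constant_weights([2.0, 3.0])
        series = g.trophic_series(wolf_rabbit_short, w, g.dirac_measure())
        np.testing.assert_allclose(series.tau, wolf_rabbit_short.N * np.array([2.0, 3.0]), rtol=1e-12)

    def test_density_series_derivative_consistent_with_tau_differences(self, wolf_rabbit_short):
        w = g.constant_weights(1.0, n=2)
        series = g.trophic_series(wolf_rabbit_short, w, g.gaussian_measure(1.0))
        dt = np.gradient(series.tau, series.t, axis=0)
        sel = series.t >= 1.0
        scale = np.max(np.abs(series.dtau_dt[sel]))
        assert np.max(np.abs(dt[sel] - series.dtau_dt[sel])) <= 1e-3 * scale

    def test_large_width_approaches_memoryless_kernel_average(self, wolf_rabbit_short):
        # as a grows, the kernel-mass-normalized history average approaches p N at t
        w = g.constant_weights(1.0, n=2)
        t = 20.0
        k = np.argmin(np.abs(wolf_rabbit_short.t - t))
        target = wolf_rabbit_short.N[k]
        gaps = []
        for a in (1.0, 10.0, 100.0, 1e4):
            meas = g.gaussian_measure(a)
            tau = g.trophic_functional(wolf_rabbit_short, w, meas, t)
            s = wolf_rabbit_short.t[wolf_rabbit_short.t <= t]
            mass = np.trapezoid(meas.w(t, s), s)
            gaps.append(np.max(np.abs(tau * t / mass - target)))
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))


class TestWeightBound:
    def test_constant_weights_within_cap(self, exp_trajectory):
        report = g.check_weight_bound(exp_trajectory, g.constant_weights(2.0, n=1, C=[3.0]))
        assert report.passed
        assert report.max_p[0] == pytest.approx(2.0)
        assert np.isnan(report.first_violation_time[0])

    def test_exponential_crossing_flagged_at_log_cap(self):
        model = g.GLVModel(r=[1.0], A=[[0.0]])
        traj = g.integrate_glv(model, [1.0], 2.0, dt_out=0.01)
        # p = N = e^t crosses C = 5 at t = ln 5
        w = g.TrophicWeights(p=lambda t, N, cumN: np.asarray(N, dtype=float), C=[5.0])
        report = g.check_weight_bound(traj, w)
        assert not report.passed
        assert report.first_violation_time[0] == pytest.approx(np.log(5.0), abs=0.011)

    def test_harmonic_weights_bounded_by_one_for_positive_rates(self):
        model = g.GLVModel(r=[1.0], A=[[0.0]])
        traj = g.integrate_glv(model, [1.0], 3.0, dt_out=0.01)
        hw = g.harmonic_weights(model)
        bounded = g.TrophicWeights(p=hw.p, dp_total=hw.dp_total, C=[1.0])
        assert g.check_weight_bound(traj, bounded).passed

    def test_missing_cap_is_configuration_error(self, exp_trajectory):
        with pytest.raises(ValueError):
            g.check_weight_bound(exp_trajectory, g.constant_weights(1.0, n=1))


class TestVolterraTriviality:
    def test_zero_kernel_annihilates_immediately(self):
        sups = g.volterra_trivial_check(lambda t, s: 0.0 * t, 1.0, 3)
        np.testing.assert_array_equal(sups, np.zeros(3))

    def test_unit_kernel_factorial_decay(self):
        # phi_k(t) = t^k / k! so the sup norm on [0, 1] is 1/k!
        sups = g.volterra_trivial_check(lambda t, s: np.ones_like(t), 1.0, 8)
        expected = 1.0 / factorial(np.arange(1, 9))
        np.testing.assert_allclose(sups, expected, atol=1e-6)

    def test_contraction_bookkeeping_for_bounded_kernel(self):
        # ||phi_{k+1}|| <= ||phi_k|| sup|K| T for K(t,s) = s on [0,1]
        sups = g.volterra_trivial_check(lambda t, s: s, 1.0, 10)
        for a, b in zip(sups, sups[1:]):
            assert b <= a * 1.0 * 1.0 + 1e-12
        assert sups[-1] < sups[0]

    def test_gaussian_memory_kernel_decays_to_zero(self):
        # the Eq-of-motion kernel (w/t - dw/dt)/w(t,t); decay is slow at first
        # (the 1/t factor is unbounded near 0) but super-exponential later
        meas = g.gaussian_measure(1.0)

        def K(t, s):
            return (meas.w(t, s) / t - meas.dw_dt(t, s)) / 1.0  # w(t, t) = 1

        sups = g.volterra_trivial_check(K, 1.0, 40, grid_size=1024)
        assert sups[39] < 1e-6
        assert sups[39] < sups[9] < sups[4]
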