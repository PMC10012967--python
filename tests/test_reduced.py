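"""Analytic reduction: exponential kernel, scalar phase equations,
phase-lag condition, existence bound, common frequency."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sepsisnet import (
    NoSynchronizedStateError,
    SyncManifoldParams,
    kappa_kernel,
    reduced_sync_rhs,
    sync_common_frequency,
    sync_existence_bound,
    sync_phase_lag,
)

ALPHA0 = -0.28 * np.pi


class TestKappaKernel:
    def test_constant_history(self):
        """For a constant phase difference d the kernel integrates to one:
        kappa = -sin(d - beta)."""
        for d, beta in [(0.0, 0.5 * np.pi), (0.7, 1.1), (-1.2, 2.5)]:
            k = kappa_kernel(lambda u, d=d: d, eps=0.1, beta=beta, t=5.0)
            assert k == pytest.approx(-np.sin(d - beta), abs=1e-8)
        assert kappa_kernel(lambda u: 0.0, eps=0.3, beta=0.5 * np.pi, t=1.0) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_uniform_drift_closed_form(self):
        """For dphi(t) = W t (history extended backward by 0 before t=0),
        the steady-state part is the convolution of the exponential kernel
        with sin(W t - beta):
        kappa_p(t) = -eps * (eps sin(A) - W cos(A)) / (eps^2 + W^2),
        A = W t - beta.  Evaluate at large t so the t<0 extension has
        decayed."""
        eps, beta, W = 0.3, 0.7, 0.9
        t = 80.0  # eps*t = 24: initial-history term < 4e-11
        a = W * t - beta
        expected = -eps * (eps * np.sin(a) - W * np.cos(a)) / (eps**2 + W**2)
        got = kappa_kernel(lambda u: W * u, eps=eps, beta=beta, t=t)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_agrees_with_adaptation_ode(self):
        """The kernel representation solves the adaptation ODE
        kappa' = -eps (kappa + sin(dphi(t) - beta)) for the same
        prescribed phases."""
        eps, beta = 0.2, 0.6

        def dphi(u):
            return 0.8 * u + 0.5 * np.sin(0.3 * u)

        k0 = kappa_kernel(dphi, eps=eps, beta=beta, t=0.0)
        sol = solve_ivp(
            lambda t, y: -eps * (y + np.sin(dphi(t) - beta)),
            (0.0, 60.0), [k0], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        for t in (5.0, 20.0, 60.0):
            assert kappa_kernel(dphi, eps=eps, beta=beta, t=t) == pytest.approx(
                float(sol.sol(t)[0]), abs=1e-6
            )


class TestReducedRHS:
    def test_zero_lag_fixed_point(self):
        d1, d2 = reduced_sync_rhs(0.4, 0.4, SyncManifoldParams(alpha0=0.0))
        assert d1 == pytest.approx(0.0, abs=1e-15)
        assert d2 == pytest.approx(0.0, abs=1e-15)

    def test_equal_frequencies_at_analytic_lag(self):
        """At the phase-lag solution both layers move at the same rate,
        which equals the closed-form common frequency."""
        p = SyncManifoldParams(alpha0=ALPHA0, sigma=1.0, beta=0.5 * np.pi)
        lag = sync_phase_lag(p)
        d1, d2 = reduced_sync_rhs(lag, 0.0, p)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 == pytest.approx(1.15576, abs=1e-5)
        assert d1 == pytest.approx(sync_common_frequency(p), abs=1e-12)

    @pytest.mark.parametrize("dphi", [-2.0, -0.3, 0.0, 0.8, 3.0])
    def test_sum_independent_of_lag(self, dphi):
        """The sigma terms cancel: d1 + d2 = -(1 + 2 sin beta) sin alpha0."""
        p = SyncManifoldParams(alpha0=ALPHA0, sigma=0.8, beta=0.62 * np.pi)
        d1, d2 = reduced_sync_rhs(1.0 + dphi, 1.0, p)
        assert d1 + d2 == pytest.approx(
            -(1 + 2 * np.sin(p.beta)) * np.sin(p.alpha0), abs=1e-12
        )


class TestPhaseLagAndBound:
    def test_reference_lag(self):
        """alpha0 = -0.28 pi, sigma = 1: interlayer lag 0.126 pi."""
        lag = sync_phase_lag(SyncManifoldParams(alpha0=ALPHA0, sigma=1.0))
        assert lag / np.pi == pytest.approx(0.12589, abs=1e-4)
        assert round(lag / np.pi, 3) == 0.126

    def test_zero_lag_for_zero_alpha(self):
        assert sync_phase_lag(SyncManifoldParams(alpha0=0.0, sigma=1.0)) == 0.0

    def test_half_sigma(self):
        """At sigma = 0.5 the lag condition reads sin(lag) = sin(0.28 pi),
        so the principal lag is exactly 0.28 pi."""
        lag = sync_phase_lag(SyncManifoldParams(alpha0=ALPHA0, sigma=0.5))
        assert lag == pytest.approx(0.28 * np.pi, abs=1e-12)

    def test_below_bound_raises(self):
        with pytest.raises(NoSynchronizedStateError, match="existence bound"):
            sync_phase_lag(SyncManifoldParams(alpha0=ALPHA0, sigma=0.3))

    @pytest.mark.parametrize(
        "alpha0, expected",
        [(ALPHA0, 0.385), (0.0, 0.0), (np.pi / 2, 0.5)],
    )
    def test_existence_bound(self, alpha0, expected):
        assert round(sync_existence_bound(alpha0), 3) == expected

    def test_bound_value_three_decimals(self):
        assert sync_existence_bound(ALPHA0) == pytest.approx(0.38526, abs=1e-5)


class TestCommonFrequency:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.5 * np.pi, 1.15576), (np.pi, 0.38525)],
    )
    def test_reference_values(self, beta, expected):
        w = sync_common_frequency(SyncManifoldParams(alpha0=ALPHA0, sigma=1.0, beta=beta))
        assert w == pytest.approx(expected, abs=1e-4)

    def test_zero_for_zero_alpha(self):
        assert sync_common_frequency(SyncManifoldParams(alpha0=0.0)) == 0.0


class TestReducedConsistency:
    def test_converges_to_analytic_lock(self):
        """Integrating the two scalar phase equations from random initial
        lags converges to the analytic phase lag and common frequency for
        20 random parameter sets satisfying the existence bound."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 20:
            alpha0 = rng.uniform(-np.pi, np.pi)
            beta = rng.uniform(0, np.pi)
            bound = sync_existence_bound(alpha0)
            sigma = rng.uniform(bound * 1.05 + 0.05, bound * 1.05 + 2.0)
            p = SyncManifoldParams(alpha0=alpha0, sigma=sigma, beta=beta)
            lag = sync_phase_lag(p)
            y0 = [rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)]

            def rhs(t, y, p=p):
                return reduced_sync_rhs(y[0], y[1], p)

            # locking rate is 2 sigma cos(lag); integrate long enough
            rate = 2 * sigma * np.cos(lag)
            t_end = max(60.0, 40.0 / rate)
            sol = solve_ivp(rhs, (0, t_end), y0, rtol=1e-10, atol=1e-12)
            d = sol.y[0, -1] - sol.y[1, -1]
            assert np.sin(d) == pytest.approx(-np.sin(alpha0) / (2 * sigma), abs=1e-6)
            f1, f2 = rhs(0.0, sol.y[:, -1])
            assert f1 == pytest.approx(f2, abs=1e-6)
            assert f1 == pytest.approx(sync_common_frequency(p), abs=1e-6)
            checked += 1

    def test_full_model_agreement(self):
        """A full duplex simulation from in-phase initial conditions ends
        at the analytic interlayer lag after the (N-1)/N finite-size
        correction (desk-scale N)."""
        from sepsisnet import DuplexState, ModelParams, detect_interlayer_locking, simulate

        n = 50
        st = DuplexState(np.zeros(n), np.zeros(n), np.zeros((n, n)), np.zeros((n, n)))
        traj = simulate(st, ModelParams(n=n), 300.0, 0.5)
        _, offsets = detect_interlayer_locking(traj, 150.0)
        corrected = np.arcsin((n - 1) / n * np.sin(0.28 * np.pi) / 2)
        assert np.abs(offsets.mean() - corrected) < 0.002 * np.pi
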