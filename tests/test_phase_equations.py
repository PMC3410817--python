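"""Event-driven phase equations (LL/QL/QQ) and orbital-deviation stepping."""

import numpy as np
import pytest

import isophase as ip
from isophase.phase_equations import (OrbitalState, orbital_step_lin,
                                      pheqn_ll_step, run_phase_equation)
from isophase.phase_schemes import phase_trace_scheme


def _synthetic_path(lc, n_events=400, periods=1.0, x0=None):
    T = lc.period
    times = np.linspace(periods * T / n_events, periods * T, n_events)
    reacts = 1 + (np.arange(n_events) % 4)
    x0 = lc.samples[0] if x0 is None else x0
    return ip.SSAPath(t_start=0.0, x0=x0, times=times,
                      reactions=reacts, seed=None)


class TestLLStep:
    def test_update_decomposition(self, brusselator, brusselator_cycle,
                                  brusselator_iso):
        # t_hat' - t_hat = tau + v.(S e_j) - tau * v.(S a(x_s))
        lc, iso = brusselator_cycle, brusselator_iso
        t_hat, tau, j = 123.4, 0.8, 3
        out = pheqn_ll_step(brusselator, lc, iso, t_hat, tau, j)
        v = iso.eval_v(t_hat)
        jump = v @ brusselator.stoich[:, j - 1]
        compensation = v @ brusselator.drift(lc.eval(t_hat))
        assert out - t_hat == pytest.approx(tau + jump - tau * compensation,
                                            rel=1e-12)

    def test_expected_increment_is_zero(self, brusselator, brusselator_cycle,
                                        brusselator_iso):
        # E[S e_j - a tau] = 0 when j ~ a/a0 and tau ~ Exp(a0)
        lc, iso = brusselator_cycle, brusselator_iso
        t_hat = 200.0
        xs = lc.eval(t_hat)
        a = brusselator.propensities(np.maximum(xs, 0.0), continuous=True)
        a0 = a.sum()
        rng = np.random.default_rng(6)
        n = 40_000
        js = rng.choice(4, size=n, p=a / a0)
        taus = rng.exponential(1 / a0, size=n)
        incr = brusselator.stoich[:, js].T - np.outer(taus, brusselator.stoich @ a)
        mc = 4 * incr.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(incr.mean(axis=0)) < mc)

    def test_input_validation(self, brusselator, brusselator_cycle,
                              brusselator_iso):
        with pytest.raises(ValueError):
            pheqn_ll_step(brusselator, brusselator_cycle, brusselator_iso,
                          0.0, -1.0, 1)
        with pytest.raises(ValueError):
            pheqn_ll_step(brusselator, brusselator_cycle, brusselator_iso,
                          0.0, 1.0, 9)


class TestOrbitalStep:
    def test_zero_state_zero_noise_is_fixed_point(self, brusselator,
                                                  brusselator_cycle,
                                                  brusselator_iso):
        st = OrbitalState(Y=np.zeros(2), t_hat=50.0)
        out = orbital_step_lin(brusselator, brusselator_cycle, brusselator_iso,
                               st, 0.5, 2, include_noise=False)
        assert np.allclose(out.Y, 0.0)

    def test_projection_annihilates_tangential_noise(self, brusselator,
                                                     brusselator_cycle,
                                                     brusselator_iso):
        # with the G-term excluded (tau=0), v.(Y' - Y) = 0 exactly
        lc, iso = brusselator_cycle, brusselator_iso
        t_hat = 321.0
        st = OrbitalState(Y=np.array([0.5, -0.3]), t_hat=t_hat)
        out = orbital_step_lin(brusselator, lc, iso, st, 0.0, 1)
        v = iso.eval_v(t_hat)
        b = brusselator.stoich[:, 0].astype(float)
        # exact up to the spline interpolation error of v^T u = 1
        assert abs(v @ (out.Y - st.Y)) < 1e-6 * abs(v @ b) + 1e-12

    def test_noise_free_stepping_matches_variational_flow(
            self, brusselator, brusselator_cycle, brusselator_iso):
        # with noise off, the orbital step is the Euler discretization of the
        # variational equation: compare against an accurate variational solve
        from scipy.integrate import solve_ivp
        lc, iso = brusselator_cycle, brusselator_iso
        horizon = lc.period / 4
        n_steps = 4000
        tau = horizon / n_steps
        Y0 = np.array([1e-3, -2e-3])
        st = OrbitalState(Y=Y0.copy(), t_hat=0.0)
        for _ in range(n_steps):
            st = orbital_step_lin(brusselator, lc, iso, st, tau, 1,
                                  include_noise=False)
            st.t_hat += tau
        ref = solve_ivp(
            lambda t, y: brusselator.jacobian(lc.eval(t)) @ y,
            (0.0, horizon), Y0, rtol=1e-10, atol=1e-14, method="LSODA",
        ).y[:, -1]
        contraction = np.linalg.norm(ref) / np.linalg.norm(Y0)
        assert np.linalg.norm(st.Y) / np.linalg.norm(Y0) == pytest.approx(
            contraction, rel=0.2)


class TestRunPhaseEquation:
    def test_zero_noise_slope_is_unity(self, brusselator, brusselator_cycle,
                                       brusselator_iso):
        path = _synthetic_path(brusselator_cycle)
        for variant in ("ll", "ql"):
            tr = run_phase_equation(brusselator, brusselator_cycle,
                                    brusselator_iso, path, variant,
                                    zero_noise=True)
            slope = np.linalg.lstsq(
                np.vstack([tr.times, np.ones_like(tr.times)]).T,
                tr.phases, rcond=None)[0][0]
            assert abs(slope - 1.0) < 1e-10
            assert np.abs(tr.shifts).max() < 1e-9

    def test_ql_equals_ll_when_hessian_zero(self, brusselator,
                                            brusselator_cycle,
                                            brusselator_iso):
        lc = brusselator_cycle
        iso0 = ip.IsochronData(cycle=lc,
                               v_samples=brusselator_iso.v_samples.copy(),
                               H_samples=np.zeros_like(brusselator_iso.H_samples))
        x0 = np.round(lc.samples[0])
        path = ip.simulate_ssa(brusselator, x0=x0, t_end=lc.period / 4, seed=21)
        tr_ll = run_phase_equation(brusselator, lc, iso0, path, "ll",
                                   initial_phase=0.0)
        tr_ql = run_phase_equation(brusselator, lc, iso0, path, "ql",
                                   initial_phase=0.0)
        np.testing.assert_allclose(tr_ql.phases, tr_ll.phases, rtol=1e-12,
                                   atol=1e-9)

    def test_qq_requires_explicit_opt_in(self, brusselator, brusselator_cycle,
                                         brusselator_iso):
        path = _synthetic_path(brusselator_cycle, n_events=10)
        with pytest.raises(ValueError, match="experimental"):
            run_phase_equation(brusselator, brusselator_cycle, brusselator_iso,
                               path, "qq")
        # opted in, the zero-noise degenerate case still runs
        tr = run_phase_equation(brusselator, brusselator_cycle, brusselator_iso,
                                path, "qq", zero_noise=True,
                                allow_experimental=True)
        assert np.abs(tr.shifts).max() < 1e-9

    def test_agrees_with_brute_force_at_low_noise(self, brusselator_4x,
                                                  brusselator_4x_cycle,
                                                  brusselator_4x_iso,
                                                  scheme_opts):
        # large volume, one period: the first-order equation tracks the
        # golden reference within a few percent of the period
        net, lc, iso = brusselator_4x, brusselator_4x_cycle, brusselator_4x_iso
        T = lc.period
        x0 = np.round(lc.samples[0])
        ssa = ip.simulate_ssa(net, x0=x0, t_end=T / 4, seed=2)
        tr = run_phase_equation(net, lc, iso, ssa, "ll", initial_phase=0.0)
        trbf = phase_trace_scheme(net, lc, None, ssa, method="bf",
                                  subsample=max(1, ssa.n_events // 12),
                                  initial_phase=0.0, opts=scheme_opts)
        idx = np.searchsorted(tr.times, trbf.times)
        rms = np.sqrt(np.mean((tr.phases[idx] - trbf.phases) ** 2))
        assert rms < 0.05 * T

    def test_ensemble_mean_shift_matches_brute_force(self, brusselator_4x,
                                                     brusselator_4x_cycle,
                                                     brusselator_4x_iso,
                                                     scheme_opts):
        """Over replicates of a short window, the mean phase shift from the
        first-order equation stays within Monte-Carlo error of the mean
        brute-force shift."""
        net, lc, iso = brusselator_4x, brusselator_4x_cycle, brusselator_4x_iso
        T = lc.period
        x0 = np.round(lc.samples[0])
        n_rep = 40
        a_ll, a_bf = np.empty(n_rep), np.empty(n_rep)
        from isophase.phase_schemes import phcomp_bf
        for i in range(n_rep):
            ssa = ip.simulate_ssa(net, x0=x0, t_end=T / 20, seed=3000 + i)
            tr = run_phase_equation(net, lc, iso, ssa, "ll", initial_phase=0.0)
            a_ll[i] = tr.shifts[-1]
            x_end = ssa.state_at(net.stoich, ssa.times[-1])
            t_hat, _ = phcomp_bf(net, lc, x_end, ssa.times[-1], scheme_opts,
                                 prev_phase=tr.phases[-1])
            a_bf[i] = t_hat - ssa.times[-1]
        mc = 3 * np.sqrt(a_ll.var() / n_rep + a_bf.var() / n_rep)
        assert abs(a_ll.mean() - a_bf.mean()) < mc + 1e-3 * T

    def test_divergence_reports_event_index(self, brusselator,
                                            brusselator_cycle,
                                            brusselator_iso):
        lc = brusselator_cycle
        # force divergence with an absurd cap
        x0 = np.round(lc.samples[0])
        path = ip.simulate_ssa(brusselator, x0=x0, t_end=lc.period / 8, seed=8)
        with pytest.raises(RuntimeError, match="event"):
            run_phase_equation(brusselator, lc, brusselator_iso, path, "ql",
                               divergence_factor=1e-9)
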