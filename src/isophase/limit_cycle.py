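"""Periodic steady state of the deterministic rate equations by shooting.

The oscillator's limit cycle ``x_s(t)`` (period ``T``) is found as the root
of the boundary-value residual ``[Phi_T(x0) - x0; anchor(x0)]`` in the
unknowns ``(x0, T)``, where ``Phi`` is the ODE flow.  The anchor pins the
otherwise free phase of the cycle by requiring the drift component of the
largest-amplitude species to vanish at ``x0`` (i.e. ``x0`` sits at an
extremum of that species).  The shooting Jacobian is built from the
variational (monodromy) integration, whose eigenvalues — the Floquet
multipliers — are returned as a by-product and certify orbital stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .model_core import ContinuousSystem

logger = logging.getLogger(__name__)

__all__ = ["LimitCycle", "MonodromyResult", "NoLimitCycleError",
           "find_limit_cycle", "monodromy", "eval_cycle", "eval_tangent"]


class NoLimitCycleError(RuntimeError):
    """Shooting iteration failed to converge: no limit cycle found."""


@dataclass
class MonodromyResult:
    """State-transition matrix over one period and its Floquet multipliers."""

    matrix: np.ndarray
    multipliers: np.ndarray  # eigenvalues, sorted by |.| descending

    @property
    def nontrivial_moduli(self) -> np.ndarray:
        """Moduli of all multipliers except the one closest to 1."""
        i = int(np.argmin(np.abs(self.multipliers - 1.0)))
        return np.abs(np.delete(self.multipliers, i))


@dataclass
class LimitCycle:
    """K-point uniform-grid representation of a periodic orbit.

    ``samples[i] = x_s(grid[i])`` and ``tangents[i] = F(x_s(grid[i]))``
    exactly; off-grid evaluation is by periodic cubic splines (C^2), so
    ``eval(t + T) == eval(t)`` for any real ``t``.
    """

    period: float
    grid: np.ndarray           # K uniform times on [0, T)
    samples: np.ndarray        # (K, N)
    tangents: np.ndarray       # (K, N), exact drift at samples
    anchor_species: int = 0
    residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        T = self.period
        t_ext = np.append(self.grid, T)
        x_ext = np.vstack([self.samples, self.samples[:1]])
        u_ext = np.vstack([self.tangents, self.tangents[:1]])
        self._sx = CubicSpline(t_ext, x_ext, bc_type="periodic", axis=0)
        self._su = CubicSpline(t_ext, u_ext, bc_type="periodic", axis=0)

    @property
    def K(self) -> int:
        return int(self.grid.size)

    @property
    def n_species(self) -> int:
        return int(self.samples.shape[1])

    @property
    def amplitude(self) -> np.ndarray:
        """Peak-to-peak oscillation amplitude per species."""
        return self.samples.max(axis=0) - self.samples.min(axis=0)

    def eval(self, t) -> np.ndarray:
        """``x_s(t)``, evaluated mod T."""
        return self._sx(np.mod(t, self.period))

    def eval_tangent(self, t) -> np.ndarray:
        """``u(t) = dx_s/dt``, evaluated mod T."""
        return self._su(np.mod(t, self.period))


def eval_cycle(lc: LimitCycle, t) -> np.ndarray:
    return lc.eval(t)


def eval_tangent(lc: LimitCycle, t) -> np.ndarray:
    return lc.eval_tangent(t)


# --------------------------------------------------------------------------
# flow and variational integration
# --------------------------------------------------------------------------

def _flow_and_monodromy(system: ContinuousSystem, x0: np.ndarray, T: float,
                        rtol: float, atol) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dx/dt=F(x), dPhi/dt=G(x)Phi over [0,T] from (x0, I)."""
    N = x0.size

    def rhs(t, z):
        x, Phi = z[:N], z[N:].reshape(N, N)
        return np.concatenate([system.drift(x), (system.jacobian(x) @ Phi).ravel()])

    z0 = np.concatenate([x0, np.eye(N).ravel()])
    sol = solve_ivp(rhs, (0.0, T), z0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    zT = sol.y[:, -1]
    return zT[:N], zT[N:].reshape(N, N)


def _flow(system, x0, T, rtol, atol):
    sol = solve_ivp(lambda t, x: system.drift(x), (0.0, T), x0,
                    method="LSODA", rtol=rtol, atol=atol,
                    jac=lambda t, x: system.jacobian(x))
    if not sol.success:
        raise RuntimeError(f"flow integration failed: {sol.message}")
    return sol.y[:, -1]


def _initial_guess(system, x_start, T_hint, rtol, atol):
    """Long transient integration, then peak-to-peak period detection."""
    T0 = T_hint if T_hint is not None else 1.0
    for _ in range(8):
        horizon = 20.0 * T0
        n_pts = 4000
        sol = solve_ivp(lambda t, x: system.drift(x), (0.0, horizon), x_start,
                        t_eval=np.linspace(0, horizon, n_pts), method="LSODA",
                        rtol=rtol, atol=atol, jac=lambda t, x: system.jacobian(x))
        if not sol.success:
            raise NoLimitCycleError(f"transient integration failed: {sol.message}")
        X = sol.y.T
        tail = X[n_pts // 2:]
        amp = tail.max(axis=0) - tail.min(axis=0)
        i_star = int(np.argmax(amp))
        w = tail[:, i_star]
        if amp[i_star] <= 1e-9 * (1.0 + np.abs(tail[:, i_star]).max()):
            raise NoLimitCycleError("trajectory settles to a fixed point; no oscillation")
        pk, _ = find_peaks(w, prominence=0.25 * amp[i_star])
        t_tail = sol.t[n_pts // 2:]
        if pk.size >= 3:
            T_est = float(np.mean(np.diff(t_tail[pk])))
            return X[n_pts // 2 + pk[-1]], T_est, i_star
        T0 *= 4.0  # horizon too short to catch 3 peaks
    raise NoLimitCycleError("could not detect a periodic orbit in the transient run")


def find_limit_cycle(
    system: ContinuousSystem,
    x_guess: np.ndarray | None = None,
    T_guess: float | None = None,
    K: int = 200,
    tol: float = 1e-8,
    *,
    max_iter: int = 50,
    rtol: float = 1e-9,
    refine_guess: bool = True,
) -> LimitCycle:
    """Damped-Newton shooting for the periodic orbit of ``system``.

    Parameters
    ----------
    x_guess, T_guess:
        Optional starting point and period estimate.  When absent (or when
        ``refine_guess``), a long transient integration (20 periods) with
        peak detection supplies them and selects the anchor species.
    K:
        Number of uniform grid points stored along the period (>= 32).
    tol:
        Relative closure tolerance: ``|Phi_T(x0)-x0| <= tol * scale`` with
        ``scale`` the oscillation amplitude.

    Raises
    ------
    NoLimitCycleError
        After ``max_iter`` damped Newton steps without convergence (the
        expected outcome for non-oscillatory parameterizations).
    """
    if K < 32:
        raise ValueError("K must be at least 32")
    if x_guess is None:
        if hasattr(system, "initial_state"):
            x_guess = np.asarray(system.initial_state, dtype=float)
        else:
            raise ValueError("x_guess required for systems without initial_state")
    else:
        x_guess = np.asarray(x_guess, dtype=float)
    if T_guess is None:
        T_guess = getattr(system, "period_hint", None)

    N = x_guess.size
    atol_tr = 1e-8 * (1.0 + np.abs(x_guess).max())
    if refine_guess:
        x0, T, i_star = _initial_guess(system, x_guess, T_guess, 1e-8, atol_tr)
    else:
        if T_guess is None:
            raise ValueError("T_guess required when refine_guess=False")
        x0, T = x_guess.copy(), float(T_guess)
        i_star = int(np.argmax(np.abs(system.drift(x0)))) if N > 1 else 0
        # prefer a component whose drift is near zero at x0 (extremum anchor)
        i_star = int(np.argmin(np.abs(system.drift(x0)) / (1.0 + np.abs(x0))))

    scale = 1.0 + np.abs(x0).max()
    atol = 1e-10 * scale
    res_prev = np.inf
    for it in range(max_iter):
        xT, Phi = _flow_and_monodromy(system, x0, T, rtol, atol)
        F0 = system.drift(x0)
        r = np.concatenate([xT - x0, [F0[i_star]]])
        res = np.linalg.norm(xT - x0) / scale
        logger.debug("shooting iter %d: residual %.3e, T=%.6g", it, res, T)
        if res <= tol and abs(F0[i_star]) <= tol * scale * 10:
            break
        J = np.zeros((N + 1, N + 1))
        J[:N, :N] = Phi - np.eye(N)
        J[:N, N] = system.drift(xT)
        J[N, :N] = system.jacobian(x0)[i_star]
        J[N, N] = 0.0
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as e:
            raise NoLimitCycleError(f"singular shooting Jacobian: {e}") from e
        # damping: halve the step until the residual decreases
        lam = 1.0
        for _ in range(8):
            x_new = x0 + lam * step[:N]
            T_new = T + lam * step[N]
            if T_new > 0:
                x_try = _flow(system, x_new, T_new, rtol, atol)
                r_new = np.linalg.norm(x_try - x_new) / scale
                if r_new < max(res, res_prev):
                    break
            lam *= 0.5
        x0, T = x0 + lam * step[:N], T + lam * step[N]
        res_prev = res
    else:
        raise NoLimitCycleError(
            f"no limit cycle found: shooting did not converge in {max_iter} "
            f"iterations (last residual {res:.3e})"
        )

    # sample the converged orbit on the uniform grid
    grid = np.linspace(0.0, T, K, endpoint=False)
    sol = solve_ivp(lambda t, x: system.drift(x), (0.0, T), x0, t_eval=grid,
                    method="LSODA", rtol=rtol, atol=atol,
                    jac=lambda t, x: system.jacobian(x))
    if not sol.success:
        raise RuntimeError(f"cycle sampling failed: {sol.message}")
    samples = sol.y.T
    tangents = np.array([system.drift(x) for x in samples])
    lc = LimitCycle(
        period=float(T), grid=grid, samples=samples, tangents=tangents,
        anchor_species=i_star, residual=float(res),
        meta={"tol": tol, "rtol": rtol, "iterations": it + 1,
              "monodromy": Phi, "name": getattr(system, "name", "system")},
    )
    return lc


def monodromy(system: ContinuousSystem, lc: LimitCycle, *,
              rtol: float = 1e-10, use_cached: bool = False) -> MonodromyResult:
    """Monodromy matrix of the cycle (variational integration over [0, T]).

    For an autonomous oscillator one Floquet multiplier equals 1; a stable
    cycle has all remaining moduli below 1.
    """
    if use_cached and "monodromy" in lc.meta:
        Phi = lc.meta["monodromy"]
    else:
        atol = 1e-10 * (1.0 + np.abs(lc.samples).max())
        _, Phi = _flow_and_monodromy(system, lc.samples[0], lc.period, rtol, atol)
    ev = np.linalg.eigvals(Phi)
    order = np.argsort(-np.abs(ev))
    return MonodromyResult(matrix=Phi, multipliers=ev[order])
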