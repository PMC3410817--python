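"""Event-driven phase equations: continuous phase models stepped by SSA events.

The first-order phase model states that the instantaneous phase ``t_hat`` of
a noisy oscillator obeys ``dt_hat/dt = 1 + v(t_hat)^T b(t)`` where ``b`` is
the state-space noise excitation projected through the phase gradient.  To
compare one-to-one against a discrete SSA sample path, the white-noise
excitation is synthesized from the recorded reaction events themselves: if
reaction ``j`` fires after a waiting time ``tau``, the zero-mean increment is

    b = S [e_j - a(x_s(t_hat)) tau]

(the observed jump minus its conditional expectation — the mean drift is
already accounted for by the deterministic cycle), giving the update

    t_hat <- t_hat + tau + v(t_hat)^T S [e_j - a(x_s(t_hat)) tau].

Three variants are provided, named by (isochron order, orbital-deviation
order): ``ll`` uses the update above; ``ql`` replaces the projection vector
by ``v + H Y`` with ``Y`` the linear orbital-deviation state; ``qq`` adds
the quadratic orbital terms and is experimental (prone to divergence for
noisy oscillators; it ships behind an explicit opt-in flag).

For speed, the periodic coefficients (``x_s``, ``u``, ``v``, ``H``, ``G``,
``S a(x_s)``) are tabulated on a dense uniform grid and linearly
interpolated inside the stepping loop; a numba-compiled kernel handles the
common on-cycle case when numba is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .isochrons import IsochronData
from .limit_cycle import LimitCycle
from .model_core import ReactionNetwork
from .phase_schemes import PhaseTrace
from .simulate import SSAPath

logger = logging.getLogger(__name__)

__all__ = ["OrbitalState", "pheqn_ll_step", "orbital_step_lin", "run_phase_equation"]


@dataclass
class OrbitalState:
    """Orbital deviation ``Y`` from the in-phase cycle point, plus the phase."""

    Y: np.ndarray
    t_hat: float


def pheqn_ll_step(
    net: ReactionNetwork,
    lc: LimitCycle,
    iso: IsochronData,
    t_hat: float,
    tau: float,
    j: int,
) -> float:
    """One first-order phase update for reaction ``j`` (1-based) after ``tau``."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if not 1 <= j <= net.n_reactions:
        raise ValueError(f"reaction index {j} out of range 1..{net.n_reactions}")
    v = iso.eval_v(t_hat)
    xs = lc.eval(t_hat)
    b = net.stoich[:, j - 1] - net.drift(xs) * tau  # S e_j - S a(x_s) tau
    return float(t_hat + tau + v @ b)


def orbital_step_lin(
    net: ReactionNetwork,
    lc: LimitCycle,
    iso: IsochronData,
    state: OrbitalState,
    tau: float,
    j: int,
    eval_point_mode: str = "on_cycle",
    include_noise: bool = True,
) -> OrbitalState:
    """Explicit-Euler step of the linear orbital-deviation equation.

    ``Y' = Y + tau G Y + (I - u v^T) S [e_j - a tau]``; the projection
    removes the tangential component of the noise increment (which the
    phase variable absorbs; exact because ``v^T u = 1``).  With
    ``eval_point_mode="shifted"`` the propensities and Jacobian are
    evaluated at ``x_s(t_hat) + Y`` instead of on the cycle; with
    ``include_noise=False`` only the deterministic contraction ``tau G Y``
    is applied.
    """
    t_hat, Y = state.t_hat, state.Y
    xs = lc.eval(t_hat)
    x_eval = xs + Y if eval_point_mode == "shifted" else xs
    G = net.jacobian(x_eval)
    Y_new = Y + tau * (G @ Y)
    if include_noise:
        v = iso.eval_v(t_hat)
        u = lc.eval_tangent(t_hat)
        b = net.stoich[:, j - 1] - net.drift(x_eval) * tau
        Y_new = Y_new + b - (v @ b) * u
    return OrbitalState(Y=Y_new, t_hat=t_hat)


def _dense_tables(net, lc, iso, n_dense: int, need_H: bool, need_G: bool):
    """Uniform lookup tables over one period for the stepping loop."""
    T = lc.period
    tg = np.linspace(0.0, T, n_dense, endpoint=False)
    xs = lc.eval(tg)
    v = iso.eval_v(tg)
    u = lc.eval_tangent(tg)
    F = np.array([net.drift(x) for x in xs])  # S a(x_s) on the grid
    H = iso.eval_H(tg) if need_H else None
    G = np.array([net.jacobian(x) for x in xs]) if need_G else None
    return xs, v, u, F, H, G


def _interp(tab: np.ndarray, pos: float, n: int):
    i0 = int(pos) % n
    w = pos - int(pos)
    i1 = (i0 + 1) % n
    return (1.0 - w) * tab[i0] + w * tab[i1]


def run_phase_equation(
    net: ReactionNetwork,
    lc: LimitCycle,
    iso: IsochronData,
    path: SSAPath,
    variant: str = "ll",
    *,
    eval_point_mode: str = "on_cycle",
    initial_phase: float = 0.0,
    zero_noise: bool = False,
    max_tau: float | None = None,
    n_dense: int = 8192,
    divergence_factor: float = 10.0,
    allow_experimental: bool = False,
) -> PhaseTrace:
    """Integrate a phase equation along the events of an SSA sample path.

    Steps are dictated by the reaction occurrence times; one explicit-Euler
    step is taken per event.  Waiting times longer than ``max_tau``
    (default ``T/100``) are split into noise-free substeps so the
    periodically varying coefficients stay resolved.  ``initial_phase``
    should come from the brute-force scheme, or be 0 for a path started on
    the cycle at t=0.  With ``zero_noise`` every increment is replaced by
    its (zero) mean, so the phase advances at exactly unit rate.

    Returns a :class:`PhaseTrace` on the event times (path start prepended).
    """
    variant = variant.lower()
    if variant not in ("ll", "ql", "qq"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "qq" and not allow_experimental:
        raise ValueError(
            "the quadratic orbital-deviation variant is experimental and "
            "numerically fragile; pass allow_experimental=True to run it"
        )
    if eval_point_mode not in ("on_cycle", "shifted"):
        raise ValueError(f"unknown eval_point_mode {eval_point_mode!r}")
    need_H = variant in ("ql", "qq")
    if need_H and not iso.has_hessian:
        raise ValueError("variant needs the phase Hessian; run compute_phase_hessian")

    T = lc.period
    N = net.n_species
    if max_tau is None:
        max_tau = T / 100.0
    S = net.stoich.astype(float)
    amp_cap = divergence_factor * float(lc.amplitude.max())
    on_cycle = eval_point_mode == "on_cycle"
    track_Y = need_H or not on_cycle

    xs_tab, v_tab, u_tab, F_tab, H_tab, G_tab = _dense_tables(
        net, lc, iso, n_dense, need_H, need_G=track_Y
    )
    dt_tab = T / n_dense

    if on_cycle and variant in ("ll", "ql") and not zero_noise:
        kern = _get_eqn_kernel()
        if kern:
            H_arg = H_tab if need_H else np.zeros((1, N, N))
            G_arg = G_tab if track_Y else np.zeros((1, N, N))
            phases, bad = kern(
                path.times, path.reactions.astype(np.int64),
                float(path.t_start), float(initial_phase),
                np.ascontiguousarray(S), v_tab, u_tab, F_tab, H_arg, G_arg,
                need_H, track_Y, float(T), float(max_tau), float(amp_cap),
            )
            if bad >= 0:
                raise RuntimeError(
                    f"orbital deviation diverged or became non-finite at event {bad}"
                )
            times = np.concatenate([[path.t_start], path.times])
            return PhaseTrace(times=times,
                              phases=np.concatenate([[initial_phase], phases]),
                              method=f"pheqn-{variant}",
                              meta={"eval_point_mode": eval_point_mode})

    t_hat = float(initial_phase)
    t_prev = float(path.t_start)
    Y = np.zeros(N)
    phases = np.empty(path.n_events)

    for k in range(path.n_events):
        j = int(path.reactions[k]) - 1
        tau_total = path.times[k] - t_prev
        while tau_total > max_tau:  # noise-free substeps across long gaps
            if track_Y:
                pos = (t_hat % T) / dt_tab
                G = _interp(G_tab, pos, n_dense) if on_cycle else net.jacobian(
                    _interp(xs_tab, pos, n_dense) + Y)
                Y = Y + max_tau * (G @ Y)
            t_hat += max_tau
            tau_total -= max_tau
        tau = tau_total
        pos = (t_hat % T) / dt_tab
        v = _interp(v_tab, pos, n_dense)
        u = _interp(u_tab, pos, n_dense)
        xs = _interp(xs_tab, pos, n_dense)
        x_eval = xs if on_cycle else xs + Y
        F = _interp(F_tab, pos, n_dense) if on_cycle else net.drift(x_eval)
        b = np.zeros(N) if zero_noise else S[:, j] - F * tau
        if need_H:
            proj = v + _interp(H_tab, pos, n_dense) @ Y
        else:
            proj = v
        t_hat = t_hat + tau + proj @ b
        if track_Y:
            G = _interp(G_tab, pos, n_dense) if on_cycle else net.jacobian(x_eval)
            if variant == "qq":
                tensor = net.hessian_tensor(x_eval)
                quad = 0.5 * np.einsum("ilm,l,m->i", tensor, Y, Y)
                Y = Y + tau * (G @ Y + quad) + b - (proj @ b) * (u + G @ Y)
            else:
                Y = Y + tau * (G @ Y) + b - (v @ b) * u
            if not np.all(np.isfinite(Y)) or np.linalg.norm(Y) > amp_cap:
                raise RuntimeError(
                    f"orbital deviation diverged or became non-finite at event {k}"
                )
        if not np.isfinite(t_hat):
            raise RuntimeError(f"phase overflowed at event {k}")
        phases[k] = t_hat
        t_prev = path.times[k]

    times = np.concatenate([[path.t_start], path.times])
    return PhaseTrace(times=times, phases=np.concatenate([[initial_phase], phases]),
                      method=f"pheqn-{variant}",
                      meta={"eval_point_mode": eval_point_mode,
                            "zero_noise": zero_noise})


_EQN_KERNEL = None


def _get_eqn_kernel():
    global _EQN_KERNEL
    if _EQN_KERNEL is not None:
        return _EQN_KERNEL
    try:
        import numba
    except ImportError:
        _EQN_KERNEL = False
        return False

    @numba.njit(cache=False)
    def kernel(times, reacts, t_start, phase0, S, v_tab, u_tab, F_tab,
               H_tab, G_tab, use_H, track_Y, T, max_tau, amp_cap):  # pragma: no cover
        n = times.shape[0]
        n_dense = v_tab.shape[0]
        N = v_tab.shape[1]
        dt_tab = T / n_dense
        phases = np.empty(n)
        t_hat = phase0
        t_prev = t_start
        Y = np.zeros(N)
        Y_new = np.zeros(N)
        for k in range(n):
            tau_total = times[k] - t_prev
            while tau_total > max_tau:
                if track_Y:
                    pos = (t_hat % T) / dt_tab
                    i0 = int(pos) % n_dense
                    w = pos - int(pos)
                    i1 = (i0 + 1) % n_dense
                    for i in range(N):
                        gy = 0.0
                        for m in range(N):
                            gy += ((1.0 - w) * G_tab[i0, i, m]
                                   + w * G_tab[i1, i, m]) * Y[m]
                        Y_new[i] = Y[i] + max_tau * gy
                    for i in range(N):
                        Y[i] = Y_new[i]
                t_hat += max_tau
                tau_total -= max_tau
            tau = tau_total
            pos = (t_hat % T) / dt_tab
            i0 = int(pos) % n_dense
            w = pos - int(pos)
            i1 = (i0 + 1) % n_dense
            j = reacts[k] - 1
            dot = 0.0
            vb = 0.0
            for i in range(N):
                b_i = S[i, j] - ((1.0 - w) * F_tab[i0, i] + w * F_tab[i1, i]) * tau
                v_i = (1.0 - w) * v_tab[i0, i] + w * v_tab[i1, i]
                vb += v_i * b_i
                proj_i = v_i
                if use_H:
                    for m in range(N):
                        proj_i += ((1.0 - w) * H_tab[i0, i, m]
                                   + w * H_tab[i1, i, m]) * Y[m]
                dot += proj_i * b_i
            t_hat = t_hat + tau + dot
            if track_Y:
                norm2 = 0.0
                for i in range(N):
                    b_i = S[i, j] - ((1.0 - w) * F_tab[i0, i] + w * F_tab[i1, i]) * tau
                    u_i = (1.0 - w) * u_tab[i0, i] + w * u_tab[i1, i]
                    gy = 0.0
                    for m in range(N):
                        gy += ((1.0 - w) * G_tab[i0, i, m]
                               + w * G_tab[i1, i, m]) * Y[m]
                    Y_new[i] = Y[i] + tau * gy + b_i - vb * u_i
                for i in range(N):
                    Y[i] = Y_new[i]
                    norm2 += Y[i] * Y[i]
                if not np.isfinite(norm2) or norm2 > amp_cap * amp_cap:
                    return phases, k
            if not np.isfinite(t_hat):
                return phases, k
            phases[k] = t_hat
            t_prev = times[k]
        return phases, -1

    _EQN_KERNEL = kernel
    return kernel
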