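"""Sample-path generation: Gillespie SSA, chemical Langevin, and RRE solutions.

The SSA implementation is the direct method: exponential waiting times with
rate ``a0 = sum_j a_j`` and linear O(M) reaction selection.  Each path keeps
the full event record ``(t_k, j_k)`` the phase machinery consumes; states are
reconstructable from ``x0`` and the stoichiometry and that reconstruction is
the integrity check applied when event logs are read back from disk.

A numba-compiled kernel is used when numba is importable; the pure-Python
fallback samples the same law and is reproducible per seed, but consumes
the RNG stream differently (per event instead of in pre-drawn blocks), so
the two backends do not generate bit-identical paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import ContinuousSystem, ReactionNetwork

logger = logging.getLogger(__name__)

__all__ = ["SSAPath", "ContinuousPath", "simulate_ssa", "simulate_cle", "solve_rre"]


@dataclass
class SSAPath:
    """A discrete sample path: initial state plus ordered reaction events.

    ``reactions`` holds 1-based reaction indices (matching the unit-vector
    convention ``e_j`` of the event-driven phase updates); times are seconds.
    """

    t_start: float
    x0: np.ndarray
    times: np.ndarray          # event times, strictly increasing
    reactions: np.ndarray      # 1-based reaction index per event
    seed: int | None = None
    model_name: str = ""
    propensity_snapshots: np.ndarray | None = None  # M per event, optional
    _states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.x0 = np.asarray(self.x0)
        self.times = np.asarray(self.times, dtype=float)
        self.reactions = np.asarray(self.reactions, dtype=np.int64)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def states(self, stoich: np.ndarray) -> np.ndarray:
        """Post-event states (n_events x N), reconstructed from the events."""
        if self._states is None:
            S = np.asarray(stoich)
            incr = S.T[self.reactions - 1]  # (n_events, N)
            self._states = self.x0[None, :] + np.cumsum(incr, axis=0)
        return self._states

    def state_at(self, stoich: np.ndarray, t: float) -> np.ndarray:
        """State just after the last event at or before time ``t``."""
        k = int(np.searchsorted(self.times, t, side="right"))
        if k == 0:
            return self.x0.copy()
        return self.states(stoich)[k - 1].copy()


@dataclass
class ContinuousPath:
    """A continuous-state trajectory on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # (len(times), N)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states/times length mismatch")


# --------------------------------------------------------------------------
# SSA kernels
# --------------------------------------------------------------------------

def _ssa_python(x, t, t_end, S, pref, ridx, rmult, ff, rng, max_events):
    times, reacts = [], []
    M = S.shape[1]
    while True:
        a = pref.copy()
        for j in range(M):
            for i, m in zip(ridx[j], rmult[j]):
                a[j] *= np.polyval(ff[m], x[i])
        a = np.maximum(a, 0.0)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a0)
        if t_next <= t:  # waiting time underflow at extreme event rates
            t_next = np.nextafter(t, np.inf)
        t = t_next
        if t > t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0, a0), side="right"))
        j = min(j, M - 1)
        x = x + S[:, j]
        times.append(t)
        reacts.append(j + 1)
        if len(times) >= max_events:
            logger.warning("SSA stopped at max_events=%d before t_end", max_events)
            break
    return np.array(times), np.array(reacts, dtype=np.int64)


_NUMBA_KERNEL = None


def _get_numba_kernel():
    global _NUMBA_KERNEL
    if _NUMBA_KERNEL is not None:
        return _NUMBA_KERNEL
    try:
        import numba
    except ImportError:
        _NUMBA_KERNEL = False
        return False

    @numba.njit(cache=False)
    def kernel(x, t, t_end, S, pref, ridx, rmult, nreact, u_exp, u_sel):  # pragma: no cover
        n_draw = u_exp.shape[0]
        M = S.shape[1]
        times = np.empty(n_draw)
        reacts = np.empty(n_draw, dtype=np.int64)
        a = np.empty(M)
        k = 0
        while k < n_draw:
            a0 = 0.0
            for j in range(M):
                aj = pref[j]
                for q in range(nreact[j]):
                    xi = x[ridx[j, q]]
                    for d in range(rmult[j, q]):
                        aj *= xi - d
                if aj < 0.0:
                    aj = 0.0
                a[j] = aj
                a0 += aj
            if a0 <= 0.0:
                return times[:k], reacts[:k], x, t, 0
            t_next = t - np.log(u_exp[k]) / a0
            if t_next <= t:  # waiting time underflow at extreme event rates
                t_next = np.nextafter(t, np.inf)
            t = t_next
            if t > t_end:
                return times[:k], reacts[:k], x, t, 0
            thr = u_sel[k] * a0
            acc = 0.0
            j = M - 1
            for jj in range(M):
                acc += a[jj]
                if acc > thr:
                    j = jj
                    break
            for i in range(S.shape[0]):
                x[i] += S[i, j]
            times[k] = t
            reacts[k] = j + 1
            k += 1
        return times[:k], reacts[:k], x, t, 1  # 1: exhausted draws, continue

    _NUMBA_KERNEL = kernel
    return kernel


def simulate_ssa(
    net: ReactionNetwork,
    x0: np.ndarray | None = None,
    t_end: float = 1.0,
    seed: int | None = None,
    *,
    t_start: float = 0.0,
    record_propensities: bool = False,
    max_events: int = 50_000_000,
) -> SSAPath:
    """Gillespie direct-method simulation of the reaction network.

    Waiting times are exponential with rate ``a0(x)``; reaction ``j`` fires
    with probability ``a_j/a0``.  Returns the full event record.  With all
    propensities zero the path has zero events.  Reproducible for a fixed
    ``seed``.
    """
    x0 = net.initial_state if x0 is None else np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if np.any(x0 != np.floor(x0)):
        raise ValueError("initial state must be integer molecule numbers")
    rng = np.random.default_rng(seed)
    S = net.stoich.astype(np.float64)

    kernel = _get_numba_kernel()
    if kernel:
        M = net.n_reactions
        nreact = np.array([len(ix) for ix in net._reactant_idx], dtype=np.int64)
        width = max(1, int(nreact.max()))
        ridx = np.zeros((M, width), dtype=np.int64)
        rmult = np.zeros((M, width), dtype=np.int64)
        for j in range(M):
            ridx[j, : nreact[j]] = net._reactant_idx[j]
            rmult[j, : nreact[j]] = net._reactant_mult[j]
        x = x0.copy()
        t = t_start
        chunks_t, chunks_j = [], []
        total = 0
        chunk = 1 << 18
        while True:
            u_exp = rng.random(chunk)
            u_sel = rng.random(chunk)
            ts, js, x, t, more = kernel(
                x, t, t_end, S, net._prefactors, ridx, rmult, nreact, u_exp, u_sel
            )
            chunks_t.append(ts)
            chunks_j.append(js)
            total += ts.size
            if not more or total >= max_events:
                if more:
                    logger.warning("SSA stopped at max_events=%d before t_end", max_events)
                break
        times = np.concatenate(chunks_t)
        reacts = np.concatenate(chunks_j)
    else:
        times, reacts = _ssa_python(
            x0.copy(), t_start, t_end, S, net._prefactors,
            net._reactant_idx, net._reactant_mult, net._ff, rng, max_events,
        )

    path = SSAPath(
        t_start=t_start, x0=x0, times=times, reactions=reacts,
        seed=seed, model_name=net.name,
    )
    if record_propensities and path.n_events:
        states = path.states(net.stoich)
        snaps = np.empty((path.n_events, net.n_reactions))
        prev = x0
        for k in range(path.n_events):
            snaps[k] = net.propensities(prev)
            prev = states[k]
        path.propensity_snapshots = snaps
    return path


# --------------------------------------------------------------------------
# continuous models
# --------------------------------------------------------------------------

def simulate_cle(
    net: ReactionNetwork,
    x0: np.ndarray | None = None,
    t_end: float = 1.0,
    dt: float | None = None,
    seed: int | None = None,
    *,
    t_start: float = 0.0,
    noise_scale: float = 1.0,
) -> ContinuousPath:
    """Euler-Maruyama integration of the chemical Langevin equation.

    One step: ``x <- x + F(x) dt + B(x) sqrt(dt) z`` with ``z`` a standard
    normal M-vector and ``B(x) = S sqrt(diag(a(x)))`` (propensities clamped
    at zero when continuous states drift slightly negative).
    ``noise_scale=0`` reduces the scheme pathwise to an explicit-Euler RRE
    solve.  Default ``dt`` is ``period_hint/2000`` when the model carries a
    period hint.
    """
    x0 = net.initial_state if x0 is None else np.asarray(x0, dtype=float)
    if dt is None:
        if net.period_hint is None:
            raise ValueError("dt not given and model has no period hint")
        dt = net.period_hint / 2000.0
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil((t_end - t_start) / dt))
    times = t_start + dt * np.arange(n_steps + 1)
    times[-1] = t_end
    X = np.empty((n_steps + 1, net.n_species))
    X[0] = x0
    x = x0.copy()
    M = net.n_reactions
    for k in range(n_steps):
        h = times[k + 1] - times[k]
        x = x + net.drift(x) * h
        if noise_scale != 0.0:
            z = rng.standard_normal(M)
            x = x + noise_scale * np.sqrt(h) * (net.diffusion(X[k]) @ z)
        X[k + 1] = x
    return ContinuousPath(times, X, meta={"dt": dt, "seed": seed, "method": "euler-maruyama"})


def solve_rre(
    system: ContinuousSystem,
    x0: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    *,
    method: str = "LSODA",
) -> ContinuousPath:
    """Integrate the deterministic drift ODE on ``t_grid`` (dense output).

    Uses an adaptive stiff-capable integrator (LSODA by default) with the
    drift Jacobian supplied analytically.  Raises on integrator failure.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    sol = solve_ivp(
        lambda t, x: system.drift(x),
        (t_grid[0], t_grid[-1]),
        np.asarray(x0, dtype=float),
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=lambda t, x: system.jacobian(x),
    )
    if not sol.success:
        raise RuntimeError(f"RRE integration failed: {sol.message}")
    return ContinuousPath(sol.t, sol.y.T, meta={"rtol": rtol, "atol": atol, "method": method})
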