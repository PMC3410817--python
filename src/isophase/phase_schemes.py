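"""Instantaneous-phase computation for individual state points and traces.

Three schemes assign an isochron-theoretic phase ``t_hat`` (seconds) to a
state point ``x`` near the limit cycle:

* **brute force** (`phcomp_bf`): integrate the noiseless rate equations from
  ``x`` and from the in-phase cycle point until the off-cycle solution has
  settled onto the orbit, then measure the time shift between the two
  final-period waveforms spectrally.  No isochron approximation — the
  golden reference.
* **linear** (`phcomp_lin`): solve ``v(t_hat)^T [x - x_s(t_hat)] = 0``, the
  first-order (tangent-hyperplane) isochron approximation.
* **quadratic** (`phcomp_quad`): solve
  ``v^T d + d^T H d / 2 = 0`` with ``d = x - x_s(t_hat)``, the second-order
  (quadric) isochron approximation.

The scalar root is found by the growing-interval bisection strategy: start
from an interval of length ``d_min`` centered on the previous timepoint's
phase, double until a sign change is bracketed (capped at ``d_max``), then
bisect down to ``d_tol``.  `phase_trace_scheme` drives any of the schemes
along a whole sample path, seeding each point with the previous phase and
unwrapping the phase to a continuous branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .isochrons import IsochronData
from .limit_cycle import LimitCycle
from .model_core import ContinuousSystem
from .simulate import ContinuousPath, SSAPath

logger = logging.getLogger(__name__)

__all__ = ["SchemeOptions", "PhaseTrace", "PhaseJumpError", "PhaseConvergenceError",
           "fourier_phase_shift", "phcomp_bf", "phcomp_lin", "phcomp_quad",
           "phase_trace_scheme"]


class PhaseJumpError(RuntimeError):
    """No sign change within d_max: phase jump too large for the bracketer."""


class PhaseConvergenceError(RuntimeError):
    """Brute-force settling has not converged (increase n_per)."""


@dataclass(frozen=True)
class SchemeOptions:
    """Numerical options shared by the phase computation schemes.

    ``d_min``/``d_max``/``d_tol`` (seconds) seed, cap and stop the
    growing-interval bisection; ``n_per`` bounds the settling integration of
    the brute-force scheme (with early exit once two successive periods of
    the waveform differ by less than ``settle_tol`` relative to amplitude).
    Unset interval fields are resolved against a period as ``T/1000``,
    ``T/2`` and ``T * 1e-6``.
    """

    d_min: float | None = None
    d_max: float | None = None
    d_tol: float | None = None
    n_per: int = 20
    fourier_grid: int = 256
    rtol: float = 1e-8
    atol: float = 1e-10
    settle_tol: float = 1e-8

    def resolved(self, T: float) -> "SchemeOptions":
        opts = replace(
            self,
            d_min=self.d_min if self.d_min is not None else T / 1000.0,
            d_max=self.d_max if self.d_max is not None else T / 2.0,
            d_tol=self.d_tol if self.d_tol is not None else T * 1e-6,
        )
        if not (0 < opts.d_min < opts.d_max <= T):
            raise ValueError("need 0 < d_min < d_max <= T")
        if not (opts.d_tol < opts.d_min):
            raise ValueError("need d_tol < d_min")
        if opts.n_per < 2:
            raise ValueError("need n_per >= 2")
        return opts


@dataclass
class PhaseTrace:
    """Per-timepoint instantaneous phase along a sample path.

    ``phases`` is the unwrapped (accumulating) phase ``t_hat``; ``shifts``
    is the phase shift ``alpha = t_hat - t``.
    """

    times: np.ndarray
    phases: np.ndarray
    method: str
    options: SchemeOptions | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def shifts(self) -> np.ndarray:
        return self.phases - self.times


# --------------------------------------------------------------------------
# Fourier shift extraction
# --------------------------------------------------------------------------

def fourier_phase_shift(w_ref: np.ndarray, w_test: np.ndarray, T: float) -> float:
    """Time shift (seconds, in ``[-T/2, T/2)``) between two periodic waveforms.

    Both waveforms must be sampled on the same uniform one-period grid.  The
    shift maximizes the circular cross-correlation, computed spectrally and
    refined by maximizing the trigonometric interpolant of the correlation
    around its grid peak.  Positive shift means ``w_test`` lags ``w_ref``
    (``w_test(t) = w_ref(t - s)`` returns ``s``).
    """
    w_ref = np.asarray(w_ref, dtype=float)
    w_test = np.asarray(w_test, dtype=float)
    if w_ref.shape != w_test.shape or w_ref.ndim != 1:
        raise ValueError("waveforms must be 1-D arrays of equal length")
    K = w_ref.size
    scale = max(np.abs(w_ref).max(), np.abs(w_test).max(), 1e-300)
    a = w_ref - w_ref.mean()
    b = w_test - w_test.mean()
    if a.std() < 1e-12 * scale or b.std() < 1e-12 * scale:
        raise ValueError("constant waveform: phase shift undefined")
    A = np.fft.rfft(a)
    B = np.fft.rfft(b)
    cross = np.conj(A) * B
    corr = np.fft.irfft(cross, n=K)
    p = int(np.argmax(corr))
    dt = T / K
    freqs = np.fft.rfftfreq(K, d=dt)
    # continuous circular correlation via the trigonometric interpolant
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if K % 2 == 0:
        weights[-1] = 1.0

    def neg_corr(tau: float) -> float:
        return -float(np.real(weights @ (cross * np.exp(2j * np.pi * freqs * tau))))

    res = minimize_scalar(neg_corr, bounds=(p * dt - dt, p * dt + dt),
                          method="bounded", options={"xatol": 1e-12 * T})
    tau = float(res.x)
    return float((tau + T / 2.0) % T - T / 2.0)


# --------------------------------------------------------------------------
# brute-force scheme
# --------------------------------------------------------------------------

def _nearest_branch(t_hat: float, prev: float, T: float) -> float:
    return t_hat + T * np.round((prev - t_hat) / T)


def phcomp_bf(
    system: ContinuousSystem,
    lc: LimitCycle,
    x_point: np.ndarray,
    t0: float,
    opts: SchemeOptions | None = None,
    prev_phase: float | None = None,
) -> tuple[float, float]:
    """Brute-force phase of ``x_point`` at time ``t0``; returns ``(t_hat, alpha)``.

    Integrates the noiseless rate equations from ``x_point`` until the
    trajectory settles onto the cycle, extracts the final-period waveform of
    every species on a uniform grid and measures its shift against the
    unperturbed cycle waveform started at ``x_s(t0)``.  The per-species
    shifts are averaged after a consistency check (they are theoretically
    identical).  The phase branch nearest ``prev_phase`` is selected when
    one is supplied.
    """
    T = lc.period
    opts = (opts or SchemeOptions()).resolved(T)
    Kf = opts.fourier_grid
    tgrid = np.linspace(0.0, T, Kf, endpoint=False)
    amp = lc.amplitude
    active = amp > 1e-9 * (1.0 + np.abs(lc.samples).max(axis=0))
    if not np.any(active):
        raise ValueError("cycle has no oscillating species")

    w_ref = lc.eval(t0 + tgrid)  # (Kf, N): unperturbed solution from x_s(t0)

    x_cur = np.asarray(x_point, dtype=float)
    w_prev = None
    amp_scale = float(amp.max())
    basin_cap = 100.0 * (np.abs(lc.samples).max() + amp_scale)
    t_eval = np.append(tgrid, T)
    for p in range(opts.n_per):
        sol = solve_ivp(lambda t, x: system.drift(x), (0.0, T), x_cur,
                        t_eval=t_eval, method="LSODA",
                        rtol=opts.rtol, atol=opts.atol * (1.0 + amp_scale),
                        jac=lambda t, x: system.jacobian(x))
        if not sol.success:
            raise RuntimeError(f"settling integration failed: {sol.message}")
        w = sol.y[:, :-1].T
        x_cur = sol.y[:, -1]
        if np.abs(w).max() > basin_cap:
            raise RuntimeError("trajectory diverged: point outside the basin of attraction")
        if w_prev is not None and np.abs(w - w_prev).max() <= opts.settle_tol * amp_scale:
            w_prev = w
            break
        w_prev = w
    else:
        logger.debug("settling ran the full n_per=%d periods", opts.n_per)

    shifts = []
    for i in np.flatnonzero(active):
        shifts.append(fourier_phase_shift(w_ref[:, i], w_prev[:, i], T))
    shifts = np.asarray(shifts)
    # circular spread check (shifts may straddle the +-T/2 seam)
    ang = shifts * 2 * np.pi / T
    mean_vec = np.mean(np.exp(1j * ang))
    spread = np.abs((np.angle(np.exp(1j * ang) / mean_vec))) * T / (2 * np.pi)
    if spread.max() > 10.0 * opts.d_tol:
        raise PhaseConvergenceError(
            f"species-wise phase shifts disagree (spread {spread.max():.3g} s); "
            "not converged — increase n_per"
        )
    alpha = float(np.angle(mean_vec)) * T / (2 * np.pi)
    alpha = -alpha  # waveform lag of the test trace = negative phase shift
    t_hat = t0 + alpha
    if prev_phase is not None:
        t_hat = _nearest_branch(t_hat, prev_phase, T)
    return float(t_hat), float(t_hat - t0)


# --------------------------------------------------------------------------
# algebraic schemes
# --------------------------------------------------------------------------

def _bracket_and_bisect(f, prev_phase: float, opts: SchemeOptions) -> float:
    """Growing-interval bracketing around prev_phase, then plain bisection."""
    L = opts.d_min
    a, b = prev_phase - L / 2, prev_phase + L / 2
    fa, fb = f(a), f(b)
    while np.sign(fa) == np.sign(fb):
        if L >= opts.d_max:
            raise PhaseJumpError(
                "no sign change within d_max: phase jump too large "
                "(rerun this point with the brute-force scheme)"
            )
        L = min(2.0 * L, opts.d_max)
        a, b = prev_phase - L / 2, prev_phase + L / 2
        fa, fb = f(a), f(b)
    while (b - a) > opts.d_tol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if np.sign(fm) == np.sign(fa):
            a, fa = m, fm
        else:
            b, fb = m, fm
    return 0.5 * (a + b)


def phcomp_lin(
    lc: LimitCycle,
    iso: IsochronData,
    x_point: np.ndarray,
    prev_phase: float,
    opts: SchemeOptions | None = None,
) -> float:
    """Linear-isochron phase: root of ``v(t)^T [x - x_s(t)]`` near ``prev_phase``."""
    opts = (opts or SchemeOptions()).resolved(lc.period)
    x = np.asarray(x_point, dtype=float)

    def f(th):
        return float(iso.eval_v(th) @ (x - lc.eval(th)))

    return _bracket_and_bisect(f, float(prev_phase), opts)


def phcomp_quad(
    lc: LimitCycle,
    iso: IsochronData,
    x_point: np.ndarray,
    prev_phase: float,
    opts: SchemeOptions | None = None,
) -> float:
    """Quadratic-isochron phase: root of ``v^T d + d^T H d / 2`` near ``prev_phase``."""
    opts = (opts or SchemeOptions()).resolved(lc.period)
    if not iso.has_hessian:
        raise ValueError("IsochronData has no phase Hessian; run compute_phase_hessian")
    x = np.asarray(x_point, dtype=float)

    def g(th):
        d = x - lc.eval(th)
        return float(iso.eval_v(th) @ d + 0.5 * d @ iso.eval_H(th) @ d)

    return _bracket_and_bisect(g, float(prev_phase), opts)


# --------------------------------------------------------------------------
# trace driver
# --------------------------------------------------------------------------

def _path_points(path, stoich):
    if isinstance(path, SSAPath):
        times = np.concatenate([[path.t_start], path.times])
        if stoich is None:
            raise ValueError("stoichiometry required to expand SSA path states")
        states = np.vstack([path.x0[None, :], path.states(stoich)])
    elif isinstance(path, ContinuousPath):
        times, states = path.times, path.states
    else:
        raise TypeError(f"unsupported path type {type(path)!r}")
    return times, states


def phase_trace_scheme(
    system: ContinuousSystem,
    lc: LimitCycle,
    iso: IsochronData | None,
    path: SSAPath | ContinuousPath,
    method: str = "lin",
    opts: SchemeOptions | None = None,
    *,
    subsample: int = 1,
    initial_phase: float | None = None,
    on_jump: str = "error",
) -> PhaseTrace:
    """Phase every (subsampled) timepoint of a sample path with one scheme.

    The first timepoint is always phased by the brute-force scheme (unless
    ``initial_phase`` is supplied, e.g. 0 for a path started on the cycle at
    t=0); each later point is seeded with the previous unwrapped phase.
    ``method`` is one of ``"bf"``, ``"lin"``, ``"quad"``.

    ``on_jump`` controls what happens when the algebraic schemes fail to
    bracket a root near the previous phase (a phase jump larger than
    ``d_max``): ``"error"`` propagates the failure; ``"bf"`` re-anchors that
    single timepoint with the brute-force scheme and continues.
    """
    if method not in ("bf", "lin", "quad"):
        raise ValueError(f"unknown scheme {method!r}")
    T = lc.period
    opts = (opts or SchemeOptions()).resolved(T)
    stoich = getattr(system, "stoich", None)
    times, states = _path_points(path, stoich)
    sel = np.arange(0, times.size, max(1, int(subsample)))
    times, states = times[sel], states[sel]

    phases = np.empty(times.size)
    if initial_phase is not None:
        phases[0] = float(initial_phase)
    else:
        t_hat, _ = phcomp_bf(system, lc, states[0], times[0], opts)
        # place the first phase on the branch nearest the wall-clock time
        phases[0] = _nearest_branch(t_hat, times[0], T)
    if on_jump not in ("error", "bf"):
        raise ValueError(f"unknown on_jump policy {on_jump!r}")
    n_jumps = 0
    for k in range(1, times.size):
        prev = phases[k - 1]
        try:
            if method == "bf":
                t_hat, _ = phcomp_bf(system, lc, states[k], times[k], opts,
                                     prev_phase=prev)
            elif method == "lin":
                t_hat = phcomp_lin(lc, iso, states[k], prev, opts)
            else:
                t_hat = phcomp_quad(lc, iso, states[k], prev, opts)
        except PhaseJumpError as e:
            if on_jump == "error":
                raise PhaseJumpError(
                    f"timepoint {k} (t={times[k]:.6g} s): {e}") from e
            t_hat, _ = phcomp_bf(system, lc, states[k], times[k], opts,
                                 prev_phase=prev)
            n_jumps += 1
        except PhaseConvergenceError as e:
            raise PhaseConvergenceError(
                f"timepoint {k} (t={times[k]:.6g} s): {e}") from e
        phases[k] = _nearest_branch(t_hat, prev, T)
    return PhaseTrace(times=times, phases=phases, method=f"phcomp-{method}",
                      options=opts, meta={"subsample": int(subsample),
                                          "bf_fallbacks": n_jumps})
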