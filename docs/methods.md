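# Methods

`isophase` computes the instantaneous, isochron-theoretic phase of noisy
biochemical oscillators. This note records the models, the numerical
choices behind each stage, and what the built-in fixtures do and do not
establish about real systems.

## Models

A well-stirred reaction chamber of volume Ω (mL) holds N dynamic molecular
species coupled by M elementary reactions. Reaction j fires in `[t, t+dt)`
with probability `a_j(x) dt`; the propensities are combinatorial mass
action in **molecule numbers**: a reactant appearing with multiplicity m
contributes the falling factorial `X(X−1)···(X−m+1)`, and a reaction of
total order p carries a factor `Ω^−(p−1)`. Species held at constant counts
(reservoirs) are removed from the dynamic state; their counts fold into the
propensity prefactors and their stoichiometry rows are identically zero.

Three nested descriptions of the same network are used:

* **Discrete stochastic** — the continuous-time Markov chain sampled by the
  Gillespie direct method (exponential waiting times with rate
  `a0 = Σ a_j`, linear O(M) reaction selection).
* **Continuous stochastic (Langevin)** —
  `dx/dt = S a(x) + S √diag(a(x)) ξ(t)`, integrated by Euler–Maruyama.
* **Continuous deterministic (rate equations)** — `dx/dt = S a(x)`,
  integrated by LSODA with the analytic Jacobian.

The discrete combinatorics (`X(X−1)`, not `X²`) are kept verbatim in the
continuous models; at low molecule numbers this measurably shifts the
limit-cycle period, so the three descriptions stay mutually consistent.
Continuous states may drift slightly negative inside integrators; negative
propensity *values* are clamped at zero where a square root or a rate is
needed, while the polynomial drift is left smooth.

## Limit cycle

The periodic solution `x_s(t)` (period T) is found by damped-Newton
shooting on the residual `[Φ_T(x0) − x0; F_i*(x0)]` in the unknowns
`(x0, T)`, where Φ is the flow and the anchor row pins the free phase by
placing `x0` at an extremum of the species `i*` with the largest
oscillation amplitude (detected in a preliminary 20-period transient run,
which also seeds `T` by peak-to-peak detection). Newton steps are halved
up to 8 times until the residual decreases; convergence is
`‖Φ_T(x0) − x0‖ ≤ tol·scale` with `tol = 1e−8` by default. The shooting
Jacobian block `Φ − I` comes from the variational (monodromy) integration,
whose eigenvalues — the Floquet multipliers — certify orbital stability
(one multiplier ≈ 1, the rest inside the unit circle).

The cycle is stored as K uniform samples (default K = 200; the relaxational
Oregonator runs use K = 800 to resolve its fast segments) with periodic
cubic-spline evaluation. Tangents `u(t_i)` are exact drift evaluations, not
spline derivatives, so the normalization identity below is checked against
uncontaminated data.

## Isochron data

The phase gradient (PPV) `v(t)` is the T-periodic solution of the adjoint
variational system `dz/dt = −Gᵀ(t) z` with `vᵀu = 1`. Relaxation
oscillators make the textbook computation (one backward adjoint pass)
unusable: the variational transients within a period can span hundreds of
e-folds and overflow double precision even though both endpoints are tame.
The implementation therefore never integrates the adjoint over more than
one grid segment:

1. per-segment transition matrices `A_i = Φ(t_i → t_{i+1})` are integrated
   forward alongside the exact state;
2. the monodromy matrix based at **each** grid point is formed as the
   cyclic product of the `A_i` (renormalized to unit norm at every step,
   which leaves eigenvectors intact);
3. `v(t_i)` is the dominant left eigenvector of that product — dominant
   because every other multiplier of a stable cycle lies strictly inside
   the unit circle — normalized pointwise by `v(t_i)ᵀ u(t_i) = 1`.

No error accumulates along the period because each point gets an
independent eigenvector extraction. Since the normalization is enforced
pointwise at grid nodes, `vᵀu = 1` there is a construction invariant;
genuine accuracy is established off-construction: against the closed-form
PPV of the polar oracle (≤ 2e−8), through the off-grid spline identity, and
end-to-end through scheme agreement (below).

The phase Hessian `H(t)` (Jacobian of the PPV) obeys
`dH/dt = −GᵀH − HG − Σ_k v_k Hess_k(F)` — obtained by differentiating
`∇phaseᵀF = 1` twice. Solving this as a full-matrix boundary-value problem
fails twice over on stiff cycles: the period map of the homogeneous
equation has a unit eigenvalue exactly (the solution is only determined up
to `γ v vᵀ`), and the same intra-period transients destroy the particular
integral. Both problems disappear in a Floquet-adapted frame:

* differentiating the normalization once gives `H u = −Gᵀ v`, which fixes
  every component of `H` involving the tangent direction algebraically
  (this also resolves the `γ v vᵀ` ambiguity);
* the remaining block, `H` restricted to the stable subspace (the
  orthogonal complement of `v`, since the stable spectral projector is
  `I − u vᵀ`), satisfies the exact discrete backward recursion
  `Σ_i = M_iᵀ Σ_{i+1} M_i + r_i`, where `M_i` restricts `A_i` to the
  stable frames and `r_i` accumulates the forcing contracted with
  propagated stable directions. All factors are bounded, and cyclic sweeps
  contract with the squared nontrivial multiplier, so a handful of sweeps
  reaches a periodic fixed point.

The assembled `H` is symmetric by construction; its accuracy is validated
against the oracle's closed-form phase Hessian (≤ 7e−8) and the chain-rule
identity `H u = dv/dt` on all fixtures.

## Phase computation schemes

Given a state point `x` near the cycle at wall-clock time `t0`:

* **Brute force** (golden reference): integrate the noiseless rate
  equations from `x` until successive one-period waveform windows differ by
  less than `settle_tol` (1e−8 relative, capped at `n_per = 20` periods;
  Floquet decay makes this a few periods in practice), then measure the
  time shift of the settled window against the unperturbed cycle waveform.
  The shift maximizes the circular cross-correlation, computed spectrally
  and refined by maximizing the trigonometric interpolant of the
  correlation — near machine precision for band-limited waveforms. Shifts
  are extracted per species and averaged after a circular consistency
  check (they are theoretically identical; disagreement beyond `10·d_tol`
  raises). The Fourier window is 256 points by default; the reaction
  fixtures use 2048 because their waveforms carry more harmonics.
* **Linear / quadratic**: solve `v(θ)ᵀd(θ) = 0` or
  `v(θ)ᵀd(θ) + d(θ)ᵀH(θ)d(θ)/2 = 0` with `d = x − x_s(θ)` by the
  growing-interval strategy — an interval of length `d_min` (default
  T/1000) centered on the previous timepoint's phase is doubled (capped at
  `d_max`, default T/2) until a sign change is bracketed, then bisected to
  `d_tol` (default T·1e−6). Nearest-root selection follows from the
  centered growth. On the oracle the observed convergence orders in the
  off-cycle distance are ≈2 (linear) and ≈3 (quadratic), with the
  quadratic error smaller pointwise.

The trace driver phases a whole sample path: the first point by brute
force (unless a known phase is supplied), later points seeded with the
previous unwrapped phase. When a path jumps by more than the bracket cap
between consecutive points — which happens on very noisy paths — the
driver can either propagate the failure (default) or re-anchor that point
with the brute-force scheme (`on_jump="bf"`).

## Phase equations

The first-order phase model advances `t̂` per SSA reaction event:

    t̂ ← t̂ + τ + vᵀ(t̂) S [e_j − a(x_s(t̂)) τ],

the bracket being the observed jump minus its conditional expectation
(zero-mean by construction, so the noiseless model advances at exactly unit
rate — asserted to 1e−10). The same event-driven substitution is applied
to the orbital-deviation equation and to the second-order phase equation:
`ql` replaces the projection by `v + H Y` with `Y` stepped by
`Y ← Y + τ G Y + (I − u vᵀ) S[e_j − aτ]`; `qq` adds the quadratic orbital
terms and is experimental (disabled without an explicit flag) because its
oblique projection terms scale with `|u||v|` and diverge on noisy paths —
divergence is detected and reported with the failing event index. One step
is taken per event; gaps longer than T/100 are split into noise-free
substeps. Periodic coefficients are tabulated on an 8192-point grid and
linearly interpolated inside the hot loop (numba-compiled when available,
with an equivalent pure-Python fallback).

Propensities/Jacobians are evaluated on the cycle by default
(`eval_point_mode="on_cycle"`); `"shifted"` re-evaluates them at
`x_s(t̂) + Y`, which helps only while `Y` remains small.

## Fixtures and what they establish

* **Polar oracle** `ṙ = r(1−r²), φ̇ = ω + c(1−r²)`: unit-circle cycle,
  period 2π/ω, exact phase `(φ − c ln r)/ω` — since
  `d/dt[φ − c ln r] = ω` identically. Every isochron quantity is
  closed-form, so this fixture is the ground truth for the PPV, the phase
  Hessian, and all three schemes.
* **Brusselator** (A→X, B+X→R+Y, Y+2X→3X, X→S; k1=0.025 s⁻¹, k2=1 s⁻¹mL,
  k3=1 s⁻¹mL², k4=0.01 s⁻¹, Ω=250 mL). Published parameterizations leave
  the reservoir counts open; the defaults A=7, B=5 sit just beyond the
  Hopf threshold (scaled parameters a′=0.7, b′=2.0, condition
  b′ > 1 + a′²), giving a smooth cycle with T ≈ 1.05e3 s and ~1.2e3
  reaction events per period — the regime in which this parameterization
  is usually reported (period near 1e3 s, sparse event grids). Large
  counts (A=100, B=300) instead give a deep relaxation oscillator
  (T ≈ 5.3e3 s, molecule numbers 2–12500, ~3e6 events per period) whose
  phase slips by most of a period per cycle; the toolkit still computes
  its cycle and isochrons, but the linear-isochron methods break down
  there, as expected for a regime far outside "moderate noise".
* **Oregonator** (five reactions incl. the fourth-order 2B+2Z→Y with its
  Ω⁻³ propensity; k1=0.005, k2=k3=k4=1, k5=1.25e−4, volume presets
  12000/3200/1600 mL). Reservoir concentrations are fixed at A/Ω=0.02,
  B/Ω=0.4 across presets — chosen once to land in the oscillatory regime
  with T ≈ 4.0e4 s; the noise level then scales with volume alone.

The generators emulate intrinsic (copy-number) noise only: no extrinsic
parameter fluctuations, no cell division or volume growth, no transcription
bursting. Passing tests therefore demonstrate correctness of the phase
machinery for well-stirred mass-action kinetics, not biological realism of
any particular clock.

## Numerical defaults

| quantity | default | note |
|---|---|---|
| RRE tolerances | rtol 1e−8, atol 1e−10·scale | phase methods differentiate these solutions |
| shooting tol | 1e−8 (relative) | damped Newton, ≤50 iterations |
| cycle grid K | 200 | 400–800 for relaxational waveforms |
| PPV/Hessian rtol | 1e−10 | per-segment integrations |
| d_min, d_max, d_tol | T/1000, T/2, T·1e−6 | bracket seed/cap/stop |
| n_per / settle_tol | 20 / 1e−8 | brute-force settling with early exit |
| Fourier grid | 256 | 2048 for the reaction fixtures |
| CLE dt | T/2000 (with period hint) | plain Euler–Maruyama, no adaptivity |
| phase-equation max τ | T/100 | longer gaps split noise-free |

Test and validation problem sizes are deliberately modest (one period of
the default Brusselator, 50 brute-force anchor points, 40-replicate
ensembles); they were chosen as the smallest sizes at which the compared
quantities are statistically meaningful.

## Known limitations

* The PPV normalization at grid nodes is enforced by construction; its
  verification burden is carried by the closed-form oracle and the
  off-grid identities, not by the grid-node inner product itself.
* Brute-force phasing assumes the point lies in the cycle's basin;
  divergence is detected crudely (norm cap at 100× the cycle scale).
* RMS agreement between the linear scheme and the brute-force reference on
  one-period Brusselator paths is typically ≤1–2% of T, but individual
  sample paths containing a large phase slip (a noise-triggered extra or
  missed cycle) can exceed that.
* The quadratic-orbital phase equation (`qq`) and the shifted evaluation
  mode are unreliable on noisy paths, mirroring their known instability;
  they are provided for completeness behind explicit options.
* Non-mass-action rate laws, τ-leaping, exact master-equation solutions,
  and Hilbert-transform phase definitions are out of scope.
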