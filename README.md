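# isophase

Isochron-theoretic phase computation for discrete molecular oscillators.

Biochemical clocks — circadian circuits, glycolytic and chemical
oscillators — run on small molecule numbers, so their rhythms jitter:
every stochastic reaction event nudges the oscillator ahead of or behind
its deterministic cycle. The right way to quantify that timing error is
the *asymptotic phase*: the point `x_s(t̂)` on the deterministic limit
cycle that a noisy state `x` will eventually synchronize with, defined by
the isochron (equal-phase hypersurface) through `x`. The quantity of
interest along a stochastic sample path is the phase shift
`α(t) = t̂(t) − t`.

`isophase` implements the full stack needed to compute `t̂` for sample
paths of reaction networks:

* **Models** — mass-action reaction networks in molecule numbers (YAML
  configs), with reservoir species held constant, plus their
  reaction-rate-equation (RRE) and chemical-Langevin (CLE) limits.
* **Simulation** — Gillespie direct-method SSA with full event records,
  Euler–Maruyama CLE, stiff-capable RRE integration.
* **Limit cycle** — damped-Newton shooting for `(x_0, T)`, Floquet
  multipliers from the monodromy matrix, periodic-spline evaluation.
* **Isochron data** — the phase gradient `v(t)` (perturbation projection
  vector / infinitesimal PRC), the T-periodic adjoint solution normalized
  by `vᵀ u = 1` with `u = dx_s/dt`; and the phase Hessian `H(t)` for
  quadratic isochron approximations.
* **Phase computation schemes** (per state point): brute force (settle the
  noiseless RRE onto the cycle and measure the waveform shift spectrally
  — the golden reference), linear (`vᵀ[x − x_s(t̂)] = 0`), and quadratic
  (`vᵀd + dᵀHd/2 = 0`), solved by growing-interval bisection.
* **Phase equations** (per reaction event): event-driven SDE updates
  `t̂ ← t̂ + τ + vᵀ(t̂) S[e_j − a(x_s(t̂)) τ]` (first order), plus
  second-order variants using `v + H·Y` with an explicit orbital-deviation
  state `Y`.

Fixtures ship with the package: the Brusselator and Oregonator reaction
networks and an analytically solvable polar ("lambda–omega") oscillator
whose exact phase map `(φ − c·ln r)/ω` grounds every test.

## Worked example

Phase a one-period SSA sample path of the Brusselator against its own
deterministic cycle:

```python
import numpy as np
import isophase as ip
from isophase.phase_schemes import SchemeOptions, phase_trace_scheme

net = ip.brusselator_model()                      # A->X, B+X->R+Y, Y+2X->3X, X->S
lc = ip.find_limit_cycle(net, K=400)
print(f"period T = {lc.period:.1f} s, shooting residual = {lc.residual:.2e}")
print("Floquet multipliers:", np.round(ip.monodromy(net, lc).multipliers, 6))

iso = ip.compute_ppv(net, lc)
ip.compute_phase_hessian(net, lc, iso)
vu = np.einsum("ki,ki->k", iso.v_samples, lc.tangents)
print(f"max |v.u - 1| on the grid = {np.abs(vu - 1).max():.2e}")

ssa = ip.simulate_ssa(net, x0=np.round(lc.samples[0]), t_end=lc.period, seed=0)
print(f"SSA: {ssa.n_events} reaction events over one period")

trace = phase_trace_scheme(net, lc, iso, ssa, method="lin", initial_phase=0.0,
                           opts=SchemeOptions(fourier_grid=2048), on_jump="bf")
for t_q in (250.0, 500.0, 750.0, lc.period):
    k = np.searchsorted(trace.times, t_q) - 1
    print(f"  t = {trace.times[k]:7.1f} s   alpha = {trace.shifts[k]:+8.2f} s")
```

prints

```
period T = 1050.2 s, shooting residual = 3.05e-12
Floquet multipliers: [1.00e+00 3.56e-04]
max |v.u - 1| on the grid = 4.44e-16
SSA: 1355 reaction events over one period
  t =   249.3 s   alpha =  -248.97 s
  t =   499.8 s   alpha =  -225.88 s
  t =   747.4 s   alpha =  -120.73 s
  t =  1049.1 s   alpha =   +93.02 s
```

Reading the output: the cycle has period `T ≈ 1050 s` and is strongly
stable (nontrivial Floquet multiplier `3.6e−4`); the phase-gradient
normalization identity holds on the grid; and along this particular
stochastic realization the oscillator first falls ~250 s behind the
deterministic clock, then recovers and finishes the period ~93 s ahead —
the per-timepoint answer the phase machinery exists to provide. The
`method="bf"` (brute-force) and `method="quad"` traces, and the
event-driven variant `run_phase_equation(net, lc, iso, ssa, "ll")`, give
the same picture at different cost/accuracy trade-offs.

The same pipeline is available from the shell:

```sh
isophase fixtures -o models/
isophase simulate-ssa --model models/brusselator.yaml --t-end 1050 --seed 0 -o events.tsv
isophase limit-cycle  --model models/brusselator.yaml --K 400 -o cycle.tsv
isophase ppv          --model models/brusselator.yaml --cycle cycle.tsv -o iso.tsv
isophase phase --method lin --model models/brusselator.yaml \
    --cycle cycle.tsv --iso iso.tsv --path events.tsv --initial-phase 0 -o trace.tsv
```

All artifacts are plain TSV with `#key=value` headers; event logs carry the
stoichiometry so readers re-validate the state reconstruction invariant.

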