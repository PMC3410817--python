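"""Built-in oscillator models: Brusselator, Oregonator, and an analytic oracle.

The two reaction networks are classical autocatalytic chemical clocks
(Belousov-Zhabotinsky-type chemistry) specified as elementary mass-action
reactions in molecule numbers.  The reservoir species (A, B, R, S) are held
at constant molecule numbers; published parameterizations leave those counts
open, so the defaults here are chosen to place each model well inside its
oscillatory (Hopf-unstable) regime and are documented as package choices.

The polar oracle is a lambda-omega oscillator whose asymptotic phase is
available in closed form, making every isochron quantity exactly checkable:

    dr/dt = r (1 - r^2),   dphi/dt = omega + c (1 - r^2)

has the unit circle as limit cycle (period ``2 pi / omega``) and, since
``d/dt [phi - c ln r] = omega`` identically, the asymptotic phase of any
point with ``r > 0`` is ``(phi - c ln r) / omega`` modulo the period.  The
parameter ``c`` skews the isochrons: for ``c = 0`` they are radial spokes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ReactionNetwork, parse_model

__all__ = ["brusselator_model", "oregonator_model", "polar_oracle",
           "OracleOscillator", "OREGONATOR_VOLUME_PROFILES",
           "brusselator_config", "oregonator_config"]


def brusselator_config(volume: float = 250.0, A_count: float = 7.0,
                       B_count: float = 5.0) -> str:
    """YAML configuration for the Brusselator at the given reservoir counts.

    Rates: k1 = 0.025 s^-1, k2 = 1 s^-1 mL, k3 = 1 s^-1 mL^2,
    k4 = 0.01 s^-1; default volume 250 mL.  The reservoir counts are a
    package choice (published parameterizations leave them open): A=7, B=5
    places the model just beyond its Hopf threshold (b' = 2 > 1 + a'^2 =
    1.49) where the cycle period is ~1.05e3 s and the waveforms are smooth
    rather than relaxational, matching the reported behavior of this
    parameterization (period near 1e3 s, sample paths of ~1e3 reaction
    events per period).
    """
    x0 = max(1, round(2.5 * A_count * volume / 250.0))
    y0 = max(1, round(10.0 * B_count * volume / 250.0))
    hint = ("period_hint: 1050.0\n"
            if (float(A_count), float(B_count)) == (7.0, 5.0) else "")
    return f"""\
name: brusselator
volume: {volume}
{hint}
# reservoir counts are package defaults; published parameterizations leave
# them open.  X, Y initial counts start near the RRE fixed point.
species:
  - {{name: X, initial: {x0}}}
  - {{name: Y, initial: {y0}}}
  - {{name: A, constant: true, count: {A_count}}}
  - {{name: B, constant: true, count: {B_count}}}
  - {{name: R, constant: true, count: 100}}
  - {{name: S, constant: true, count: 100}}
reactions:
  - {{reactants: {{A: 1}}, products: {{X: 1, A: 1}}, rate: 0.025}}
  - {{reactants: {{B: 1, X: 1}}, products: {{B: 1, R: 1, Y: 1}}, rate: 1.0}}
  - {{reactants: {{Y: 1, X: 2}}, products: {{X: 3}}, rate: 1.0}}
  - {{reactants: {{X: 1}}, products: {{S: 1}}, rate: 0.01}}
"""


def brusselator_model(volume: float = 250.0, A_count: float = 7.0,
                      B_count: float = 5.0) -> ReactionNetwork:
    """Brusselator reaction network: A->X, B+X->R+Y, Y+2X->3X, X->S.

    Dynamic species (X, Y); stoichiometry [[1,-1,1,-1],[0,1,-1,0]].
    The default reservoir counts give a smooth near-Hopf limit cycle with
    period ~1.05e3 s; large counts (e.g. A=100, B=300) push the model into
    a strongly relaxational regime with a ~5.3e3 s period and molecule
    numbers spanning four orders of magnitude over the cycle.
    ``brusselator_oscillation_condition`` reports the scaled-model Hopf
    criterion for the chosen counts.
    """
    if A_count <= 0 or B_count <= 0:
        raise ValueError("reservoir counts must be positive")
    net = parse_model(brusselator_config(volume, A_count, B_count))
    if float(A_count) == 7.0 and float(B_count) == 5.0:
        net.period_hint = 1050.0  # seeds period detection only
    return net


def brusselator_oscillation_condition(net: ReactionNetwork) -> tuple[float, float]:
    """Return (a', b') of the nondimensionalized model; oscillation iff b' > 1 + a'^2.

    With rates k1..k4, reservoir counts A and B and volume W, the scaling
    x = X sqrt(k3/k4)/W, y likewise, tau = k4 t maps the rate equations onto
    the textbook form dx/dtau = a - (b+1)x + x^2 y with
    a' = (k1 A / (k4 W)) sqrt(k3/k4) and b' = k2 B/(k4 W).
    """
    k1, k2, k3, k4 = (r.rate for r in net.reactions)
    A = net.constant_counts["A"]
    B = net.constant_counts["B"]
    W = net.volume
    a_p = (k1 * A / (k4 * W)) * np.sqrt(k3 / k4)
    b_p = k2 * B / (k4 * W)
    return float(a_p), float(b_p)


#: Named Oregonator volume presets (mL): large volume is nearly
#: deterministic, the smaller two are increasingly noisy.
OREGONATOR_VOLUME_PROFILES: dict[str, float] = {
    "large": 12000.0,
    "moderate": 3200.0,
    "noisy": 1600.0,
}


def oregonator_config(volume: float = 12000.0, A_count: float | None = None,
                      B_count: float | None = None,
                      R_count: float = 1000.0) -> str:
    """YAML configuration for the Oregonator.

    Rates: k1 = 0.005 s^-1 mL, k2 = k3 = k4 = 1 s^-1 mL,
    k5 = 1.25e-4 s^-1 mL^3.  Reservoir counts default to fixed
    concentrations A/volume = 0.02, B/volume = 0.4 (package choice, giving a
    period near 4.0e4 s at every preset volume); R is a pure product and its
    count never enters the dynamics.
    """
    if A_count is None:
        A_count = 0.02 * volume
    if B_count is None:
        B_count = 0.4 * volume
    x0 = max(1, round(0.005 * volume))
    z0 = max(1, round(0.02 * volume))
    return f"""\
name: oregonator
volume: {volume}
period_hint: 40000.0
species:
  - {{name: X, initial: {x0}}}
  - {{name: Y, initial: {x0}}}
  - {{name: Z, initial: {z0}}}
  - {{name: A, constant: true, count: {A_count}}}
  - {{name: B, constant: true, count: {B_count}}}
  - {{name: R, constant: true, count: {R_count}}}
reactions:
  - {{reactants: {{A: 1, Y: 1}}, products: {{X: 1, R: 1, A: 1}}, rate: 0.005}}
  - {{reactants: {{X: 1, Y: 1}}, products: {{R: 2}}, rate: 1.0}}
  - {{reactants: {{A: 1, X: 1}}, products: {{X: 2, Z: 2, A: 1}}, rate: 1.0}}
  - {{reactants: {{X: 2}}, products: {{A: 1, R: 1}}, rate: 1.0}}
  - {{reactants: {{B: 2, Z: 2}}, products: {{Y: 1, B: 2}}, rate: 1.25e-4}}
"""


def oregonator_model(volume: float = 12000.0, A_count: float | None = None,
                     B_count: float | None = None,
                     R_count: float = 1000.0) -> ReactionNetwork:
    """Oregonator network: A+Y->X+R, X+Y->2R, A+X->2X+2Z, 2X->A+R, 2B+2Z->Y.

    Dynamic species (X, Y, Z).  Reaction 5 is fourth order overall, so its
    propensity carries a 1/volume^3 factor and the two-Z combinatorial
    Z(Z-1) form.  Reservoir counts scale with volume by default so the
    deterministic cycle (period ~4.0e4 s) is shared by all presets while
    the noise level varies.  A stiff integrator profile is appropriate:
    the waveforms are relaxation-type.
    """
    return parse_model(oregonator_config(volume, A_count, B_count, R_count))


@dataclass
class OracleOscillator:
    """Lambda-omega oscillator with closed-form isochrons (Cartesian coords).

    ``c`` skews the isochrons (0 = radial); ``omega`` is the angular
    frequency, so the period is ``2 pi / omega``.  Implements the
    continuous-system contract (drift/jacobian/hessian_tensor) plus the
    exact asymptotic phase and its first two derivatives for use as ground
    truth.
    """

    c: float = 0.0
    omega: float = 1.0
    name: str = "polar-oracle"
    n_species: int = field(default=2, init=False)

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        self.period_hint = 2.0 * np.pi / self.omega
        self.initial_state = np.array([1.0, 0.0])

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    def drift(self, xy) -> np.ndarray:
        x, y = np.asarray(xy, dtype=float)
        s = 1.0 - (x * x + y * y)
        return np.array([s * (x - self.c * y) - self.omega * y,
                         s * (y + self.c * x) + self.omega * x])

    def jacobian(self, xy) -> np.ndarray:
        x, y = np.asarray(xy, dtype=float)
        c, w = self.c, self.omega
        s = 1.0 - (x * x + y * y)
        g = x - c * y
        h = y + c * x
        return np.array([
            [-2 * x * g + s, -2 * y * g - c * s - w],
            [-2 * x * h + c * s + w, -2 * y * h + s],
        ])

    def hessian_tensor(self, xy) -> np.ndarray:
        x, y = np.asarray(xy, dtype=float)
        c = self.c
        g = x - c * y
        h = y + c * x
        H1 = np.array([[-2 * g - 4 * x, 2 * c * x - 2 * y],
                       [2 * c * x - 2 * y, -2 * g + 4 * c * y]])
        H2 = np.array([[-2 * h - 4 * c * x, -2 * x - 2 * c * y],
                       [-2 * x - 2 * c * y, -2 * h - 4 * y]])
        return np.stack([H1, H2])

    # -- closed-form ground truth ----------------------------------------
    def analytic_phase(self, xy) -> float:
        """Asymptotic phase (seconds in [0, T)) of a point with r > 0."""
        x, y = np.asarray(xy, dtype=float)
        r2 = x * x + y * y
        if r2 <= 0.0:
            raise ValueError("phase undefined at the origin (phaseless set)")
        psi = np.arctan2(y, x) - 0.5 * self.c * np.log(r2)
        return float((psi / self.omega) % self.period)

    def analytic_ppv(self, xy) -> np.ndarray:
        """Gradient of the asymptotic-phase function at any r > 0."""
        x, y = np.asarray(xy, dtype=float)
        r2 = x * x + y * y
        if r2 <= 0.0:
            raise ValueError("gradient undefined at the origin")
        return np.array([(-y - self.c * x), (x - self.c * y)]) / (r2 * self.omega)

    def analytic_phase_hessian(self, xy) -> np.ndarray:
        """Second-derivative matrix of the asymptotic-phase function."""
        x, y = np.asarray(xy, dtype=float)
        r2 = x * x + y * y
        if r2 <= 0.0:
            raise ValueError("Hessian undefined at the origin")
        r4 = r2 * r2
        c, w = self.c, self.omega
        phi_xx, phi_xy, phi_yy = 2 * x * y / r4, (y * y - x * x) / r4, -2 * x * y / r4
        lnr_xx, lnr_xy, lnr_yy = (y * y - x * x) / r4, -2 * x * y / r4, (x * x - y * y) / r4
        H = np.array([[phi_xx - c * lnr_xx, phi_xy - c * lnr_xy],
                      [phi_xy - c * lnr_xy, phi_yy - c * lnr_yy]])
        return H / w


def polar_oracle(c: float = 0.0, omega: float = 1.0) -> OracleOscillator:
    """Construct the analytic polar oscillator fixture."""
    return OracleOscillator(c=c, omega=omega)
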