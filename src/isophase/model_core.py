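"""Stochastic chemical kinetics models and their continuous-state limits.

A :class:`ReactionNetwork` represents a well-stirred reaction chamber of
volume ``volume`` (mL) containing ``N`` dynamic molecular species coupled by
``M`` elementary mass-action reactions.  The network exposes everything the
downstream oscillator-phase machinery needs:

* discrete-state propensities ``a_j(x)`` (combinatorial mass action, with
  the exact ``X(X-1)`` convention for second-order self interactions),
* the deterministic drift ``F(x) = S a(x)`` of the reaction rate equation,
* its Jacobian ``G(x)`` and second-derivative tensor,
* the state-dependent diffusion factor ``B(x) = S sqrt(diag(a(x)))`` of the
  chemical Langevin equation.

Species whose molecule numbers are held constant (reservoir species) are
removed from the dynamic state; their counts are folded into the propensity
prefactors, and they contribute zero stoichiometry.

All quantities are expressed in molecule numbers, never concentrations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParseError",
    "Reaction",
    "ReactionNetwork",
    "ContinuousSystem",
    "FunctionSystem",
    "parse_model",
    "serialize_model",
    "propensities",
    "drift_field",
    "drift_jacobian",
    "drift_hessian_tensor",
    "diffusion_matrix",
]


class ModelParseError(ValueError):
    """Raised when a model configuration is malformed; names the offending key."""


def _falling_factorial_coeffs(m: int) -> np.ndarray:
    """Polynomial coefficients (highest power first) of x(x-1)...(x-m+1)."""
    if m == 0:
        return np.array([1.0])
    return np.poly(np.arange(m, dtype=float))


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction with mass-action kinetics.

    ``reactants``/``products`` map species names to stoichiometric
    multiplicities.  ``rate`` is the stochastic rate constant ``k_j`` whose
    units absorb the reaction order (s^-1 mL^(order-1)).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: float

    @property
    def order(self) -> int:
        return int(sum(self.reactants.values()))


@runtime_checkable
class ContinuousSystem(Protocol):
    """Contract for any smooth autonomous ODE oscillator ``dx/dt = F(x)``.

    Implemented by :class:`ReactionNetwork` (reaction-rate-equation drift)
    and by analytic fixtures; consumed by the limit-cycle, isochron and
    phase modules, which only ever need these four members.
    """

    n_species: int

    def drift(self, x: np.ndarray) -> np.ndarray: ...

    def jacobian(self, x: np.ndarray) -> np.ndarray: ...

    def hessian_tensor(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class FunctionSystem:
    """Adapter wrapping plain callables into a :class:`ContinuousSystem`."""

    n_species: int
    drift_fn: Callable[[np.ndarray], np.ndarray]
    jacobian_fn: Callable[[np.ndarray], np.ndarray]
    hessian_fn: Callable[[np.ndarray], np.ndarray]
    period_hint: float | None = None
    name: str = "system"

    def drift(self, x):
        return np.asarray(self.drift_fn(np.asarray(x, dtype=float)), dtype=float)

    def jacobian(self, x):
        return np.asarray(self.jacobian_fn(np.asarray(x, dtype=float)), dtype=float)

    def hessian_tensor(self, x):
        return np.asarray(self.hessian_fn(np.asarray(x, dtype=float)), dtype=float)


@dataclass
class ReactionNetwork:
    """A mass-action reaction network over dynamic + constant species.

    Attributes
    ----------
    species_names:
        Names of the ``N`` dynamic species (state-vector ordering).
    constant_counts:
        Molecule numbers of reservoir species held constant.
    stoich:
        ``N x M`` integer matrix; column ``j`` is the state change of
        reaction ``j``.
    reactions:
        The parsed reactions (including constant-species participation).
    volume:
        Chamber volume (mL), strictly positive.
    initial_state:
        Default initial molecule numbers for the dynamic species.
    """

    species_names: list[str]
    constant_counts: dict[str, float]
    stoich: np.ndarray
    reactions: list[Reaction]
    volume: float
    initial_state: np.ndarray
    name: str = "network"
    period_hint: float | None = None
    # derived propensity tables, built in __post_init__
    _prefactors: np.ndarray = field(init=False, repr=False)
    _reactant_idx: list[np.ndarray] = field(init=False, repr=False)
    _reactant_mult: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        self.stoich = np.asarray(self.stoich, dtype=int)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.volume <= 0:
            raise ModelParseError("volume: must be positive")
        if not self.reactions:
            raise ModelParseError("reactions: model defines zero reactions")
        if self.stoich.shape != (self.n_species, self.n_reactions):
            raise ModelParseError("stoich: shape inconsistent with species/reactions")
        name_to_idx = {s: i for i, s in enumerate(self.species_names)}
        pref, ridx, rmult = [], [], []
        for r in self.reactions:
            c = float(r.rate) / self.volume ** (r.order - 1)
            idx, mult = [], []
            for sp, m in r.reactants.items():
                if sp in self.constant_counts:
                    cnt = self.constant_counts[sp]
                    c *= float(np.polyval(_falling_factorial_coeffs(int(m)), cnt))
                else:
                    idx.append(name_to_idx[sp])
                    mult.append(int(m))
            pref.append(c)
            ridx.append(np.array(idx, dtype=int))
            rmult.append(np.array(mult, dtype=int))
        self._prefactors = np.array(pref)
        self._reactant_idx = ridx
        self._reactant_mult = rmult
        # cache falling-factorial polynomial coeffs and derivatives per order
        max_m = max((int(m) for mm in rmult for m in mm), default=1)
        self._ff = [_falling_factorial_coeffs(m) for m in range(max_m + 1)]
        self._ffd = [np.polyder(p) for p in self._ff]
        self._ffdd = [np.polyder(p, 2) for p in self._ff]

    # -- basic shape info -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- propensities and continuous-state derivatives --------------------
    def propensities(self, x: np.ndarray, *, continuous: bool = False) -> np.ndarray:
        """Mass-action propensities ``a_j(x)``, length ``M``.

        Discrete use (default) rejects negative molecule numbers.  With
        ``continuous=True`` slightly negative states from ODE/SDE
        integrators are tolerated and any negative propensity value is
        clamped at zero (with a debug log), keeping the noise amplitudes
        of the Langevin model well defined.
        """
        x = np.asarray(x, dtype=float)
        if not continuous and np.any(x < 0):
            raise ValueError("negative molecule number in state vector")
        a = self._raw_propensities(x)
        if continuous:
            neg = a < 0
            if np.any(neg):
                logger.debug("clamped %d negative propensities at 0", int(neg.sum()))
                a = np.where(neg, 0.0, a)
        return a

    def _raw_propensities(self, x: np.ndarray) -> np.ndarray:
        a = self._prefactors.copy()
        for j in range(self.n_reactions):
            for i, m in zip(self._reactant_idx[j], self._reactant_mult[j]):
                a[j] *= np.polyval(self._ff[m], x[i])
        return a

    def drift(self, x: np.ndarray) -> np.ndarray:
        """RRE drift ``F(x) = S a(x)`` (raw polynomial, smooth in x)."""
        x = np.asarray(x, dtype=float)
        return self.stoich @ self._raw_propensities(x)

    def propensity_jacobian(self, x: np.ndarray) -> np.ndarray:
        """``M x N`` matrix of d a_j / d x_i (analytic)."""
        x = np.asarray(x, dtype=float)
        J = np.zeros((self.n_reactions, self.n_species))
        for j in range(self.n_reactions):
            idx, mult = self._reactant_idx[j], self._reactant_mult[j]
            vals = [np.polyval(self._ff[m], x[i]) for i, m in zip(idx, mult)]
            for p, (i, m) in enumerate(zip(idx, mult)):
                term = self._prefactors[j] * np.polyval(self._ffd[m], x[i])
                for q, v in enumerate(vals):
                    if q != p:
                        term *= v
                J[j, i] += term
        return J

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Drift Jacobian ``G(x) = d(S a)/dx``, shape ``N x N``."""
        return self.stoich @ self.propensity_jacobian(x)

    def hessian_tensor(self, x: np.ndarray) -> np.ndarray:
        """Second derivatives ``T[i,l,m] = d^2 (S a)_i / dx_l dx_m``."""
        x = np.asarray(x, dtype=float)
        N, M = self.n_species, self.n_reactions
        out = np.zeros((N, N, N))
        for j in range(M):
            idx, mult = self._reactant_idx[j], self._reactant_mult[j]
            k = len(idx)
            if k == 0:
                continue
            vals = [np.polyval(self._ff[m], x[i]) for i, m in zip(idx, mult)]
            dvals = [np.polyval(self._ffd[m], x[i]) for i, m in zip(idx, mult)]
            ddvals = [np.polyval(self._ffdd[m], x[i]) for i, m in zip(idx, mult)]
            aH = np.zeros((N, N))
            for p in range(k):
                for q in range(k):
                    if idx[p] == idx[q] and p != q:
                        continue  # same dynamic species cannot appear twice as separate entries
                    term = self._prefactors[j]
                    if p == q:
                        term *= ddvals[p]
                    else:
                        term *= dvals[p] * dvals[q]
                    for r in range(k):
                        if r != p and r != q:
                            term *= vals[r]
                    aH[idx[p], idx[q]] += term
            out += np.einsum("i,lm->ilm", self.stoich[:, j].astype(float), aH)
        return out

    def diffusion(self, x: np.ndarray) -> np.ndarray:
        """CLE diffusion factor ``B(x)``: column ``j`` is ``s_j sqrt(a_j)``."""
        a = self.propensities(x, continuous=True)
        return self.stoich * np.sqrt(a)[None, :]

    def equilibrium(self, x_guess: np.ndarray | None = None) -> np.ndarray:
        """A root of ``S a(x) = 0`` near ``x_guess`` (Newton via scipy)."""
        from scipy.optimize import fsolve

        x0 = self.initial_state if x_guess is None else np.asarray(x_guess, float)
        sol, info, ok, msg = fsolve(self.drift, x0, fprime=self.jacobian, full_output=True)
        if ok != 1:
            raise RuntimeError(f"equilibrium search failed: {msg}")
        return sol


# --------------------------------------------------------------------------
# module-level functional surface
# --------------------------------------------------------------------------

def propensities(net: ReactionNetwork, x, **kw) -> np.ndarray:
    return net.propensities(x, **kw)


def drift_field(net: ContinuousSystem, x) -> np.ndarray:
    return net.drift(np.asarray(x, dtype=float))


def drift_jacobian(net: ContinuousSystem, x) -> np.ndarray:
    return net.jacobian(np.asarray(x, dtype=float))


def drift_hessian_tensor(net: ContinuousSystem, x) -> np.ndarray:
    return net.hessian_tensor(np.asarray(x, dtype=float))


def diffusion_matrix(net: ReactionNetwork, x) -> np.ndarray:
    return net.diffusion(np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# YAML model configuration
# --------------------------------------------------------------------------

def parse_model(config_text: str) -> ReactionNetwork:
    """Parse a YAML model configuration into a :class:`ReactionNetwork`.

    The document must define ``species`` (each with ``name`` and either an
    ``initial`` molecule number or ``constant: true`` with a ``count``),
    ``reactions`` (each with ``reactants``, ``products`` and ``rate``) and
    ``volume`` in mL.  Raises :class:`ModelParseError` naming the offending
    key on malformed input.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as e:  # pragma: no cover - yaml diagnostics
        raise ModelParseError(f"yaml: {e}") from e
    if not isinstance(doc, dict):
        raise ModelParseError("document: expected a mapping")
    try:
        volume = float(doc["volume"])
    except (KeyError, TypeError, ValueError):
        raise ModelParseError("volume: missing or non-numeric")
    if volume <= 0:
        raise ModelParseError("volume: must be positive")

    species_entries = doc.get("species")
    if not species_entries:
        raise ModelParseError("species: missing or empty")
    dyn_names: list[str] = []
    initial: list[float] = []
    constant: dict[str, float] = {}
    for ent in species_entries:
        if "name" not in ent:
            raise ModelParseError("species.name: missing")
        nm = str(ent["name"])
        if ent.get("constant", False):
            if "count" not in ent:
                raise ModelParseError(f"species.{nm}.count: constant species needs a count")
            constant[nm] = float(ent["count"])
        else:
            dyn_names.append(nm)
            initial.append(float(ent.get("initial", 0)))
    known = set(dyn_names) | set(constant)

    rx_entries = doc.get("reactions")
    if not rx_entries:
        raise ModelParseError("reactions: missing or empty (zero reactions)")
    reactions: list[Reaction] = []
    for k, ent in enumerate(rx_entries):
        for side in ("reactants", "products"):
            for sp, m in (ent.get(side) or {}).items():
                if sp not in known:
                    raise ModelParseError(f"reactions[{k}].{side}.{sp}: unknown species")
                if int(m) != m:
                    raise ModelParseError(f"reactions[{k}].{side}.{sp}: non-integer stoichiometry")
        if "rate" not in ent:
            raise ModelParseError(f"reactions[{k}].rate: missing")
        reactions.append(
            Reaction(
                reactants={str(s): int(m) for s, m in (ent.get("reactants") or {}).items()},
                products={str(s): int(m) for s, m in (ent.get("products") or {}).items()},
                rate=float(ent["rate"]),
            )
        )

    N, M = len(dyn_names), len(reactions)
    name_to_idx = {s: i for i, s in enumerate(dyn_names)}
    S = np.zeros((N, M), dtype=int)
    for j, r in enumerate(reactions):
        for sp, m in r.reactants.items():
            if sp in name_to_idx:
                S[name_to_idx[sp], j] -= int(m)
        for sp, m in r.products.items():
            if sp in name_to_idx:
                S[name_to_idx[sp], j] += int(m)
    for j in range(M):
        if N and not np.any(S[:, j]):
            warnings.warn(
                f"reaction {j + 1} does not change any dynamic species", stacklevel=2
            )
    return ReactionNetwork(
        species_names=dyn_names,
        constant_counts=constant,
        stoich=S,
        reactions=reactions,
        volume=volume,
        initial_state=np.array(initial, dtype=float),
        name=str(doc.get("name", "network")),
        period_hint=float(doc["period_hint"]) if "period_hint" in doc else None,
    )


def serialize_model(net: ReactionNetwork) -> str:
    """Emit the YAML configuration of a network (parse/serialize round trip)."""
    species = [
        {"name": nm, "initial": float(x0)}
        for nm, x0 in zip(net.species_names, net.initial_state)
    ] + [
        {"name": nm, "constant": True, "count": float(c)}
        for nm, c in net.constant_counts.items()
    ]
    doc = {
        "name": net.name,
        "volume": float(net.volume),
        "species": species,
        "reactions": [
            {
                "reactants": {s: int(m) for s, m in r.reactants.items()},
                "products": {s: int(m) for s, m in r.products.items()},
                "rate": float(r.rate),
            }
            for r in net.reactions
        ],
    }
    if net.period_hint is not None:
        doc["period_hint"] = float(net.period_hint)
    return yaml.safe_dump(doc, sort_keys=False)
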