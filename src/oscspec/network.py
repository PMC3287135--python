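"""Reaction-network model: definition, validation and transformations.

A :class:`ReactionNetwork` is an ordered list of species and reactions with
either mass-action or custom kinetic laws.  Networks exist in one of two unit
modes:

``concentration``
    initial amounts are concentrations (mol/l) and rate constants carry the
    usual deterministic units;
``count``
    initial amounts are integer molecule counts and rate constants are
    stochastic (per-molecule) rates, the form required by the stochastic
    simulator.

:func:`discretize` converts between the two using a single constant ``alpha``
(units l/mol): counts = alpha * concentration, and a mass-action rate constant
of total order m is divided by alpha**(m-1).

:func:`to_quasi_deterministic` replaces the elemental reaction channels by one
resultant birth/death channel pair per species whose net rate equals the net
drift of the source network at every state, drastically reducing intrinsic
noise while preserving the instantaneous expected motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "KineticLaw",
    "Reaction",
    "ReactionNetwork",
    "DiscretizationConfig",
    "validate_network",
    "discretize",
    "stoichiometry",
    "to_quasi_deterministic",
    "propensity",
    "propensities",
    "drift",
    "deterministic_rhs",
]

# functions available inside custom rate expressions
_EXPR_FUNCS = {
    "max": max,
    "min": min,
    "abs": abs,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "pow": pow,
}


@dataclass
class Species:
    """A molecular species with its initial amount.

    ``initial_amount`` is a concentration (mol/l) in concentration mode and a
    non-negative integer molecule count in count mode.
    """

    name: str
    initial_amount: float = 0.0


@dataclass
class KineticLaw:
    """Kinetic law of a reaction.

    ``form="mass_action"`` uses ``rate_constant`` with the combinatorial
    propensity (falling factorials over reactant multiplicities, plain counts
    for modifiers).  ``form="custom"`` evaluates ``rate_expression`` — either
    an arithmetic expression string over species names (with max/min/abs/exp/
    log/sqrt available) or a Python callable taking a mapping of species name
    to amount — and uses its value directly as the propensity.
    """

    form: str = "mass_action"
    rate_constant: float | None = None
    rate_expression: str | Callable | None = None

    def __post_init__(self) -> None:
        if self.form not in ("mass_action", "custom"):
            raise ValueError(f"unknown kinetic law form {self.form!r}")
        if self.form == "custom" and isinstance(self.rate_expression, str):
            # compile once; evaluated against a species namespace
            self._code = compile(self.rate_expression, "<rate>", "eval")
        else:
            self._code = None

    def evaluate(self, namespace: Mapping[str, float]) -> float:
        """Evaluate a custom law at a state given as name -> amount."""
        if self.form != "custom":
            raise ValueError("evaluate() only applies to custom laws")
        if callable(self.rate_expression):
            return float(self.rate_expression(namespace))
        env = dict(_EXPR_FUNCS)
        env.update(namespace)
        return float(eval(self._code, {"__builtins__": {}}, env))


@dataclass
class Reaction:
    """One reaction channel.

    ``reactants`` and ``products`` are multisets (name -> multiplicity >= 1);
    ``modifiers`` are catalytic species that affect the rate but have zero net
    stoichiometry.  Modifiers are explicit rather than written as
    reactant+product pairs so that their stoichiometry column entry is exactly
    zero.
    """

    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    modifiers: dict[str, int] = field(default_factory=dict)
    kinetics: KineticLaw = field(default_factory=KineticLaw)
    name: str | None = None

    def net_change(self) -> dict[str, int]:
        """Net stoichiometric change per species (zero entries dropped)."""
        delta: dict[str, int] = {}
        for sp, m in self.products.items():
            delta[sp] = delta.get(sp, 0) + m
        for sp, m in self.reactants.items():
            delta[sp] = delta.get(sp, 0) - m
        return {sp: d for sp, d in delta.items() if d != 0}

    def order(self) -> int:
        """Total kinetic order: reactant plus modifier multiplicities."""
        return sum(self.reactants.values()) + sum(self.modifiers.values())


@dataclass
class DiscretizationConfig:
    """Concentration -> molecule-count conversion constant alpha (l/mol)."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass
class ReactionNetwork:
    """An ordered reaction network; species order fixes state-vector indexing."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    units_mode: str = "count"
    name: str = ""

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in network") from None

    def initial_state(self) -> np.ndarray:
        if self.units_mode == "count":
            return np.array(
                [int(round(s.initial_amount)) for s in self.species], dtype=np.int64
            )
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def has_custom_laws(self) -> bool:
        return any(r.kinetics.form == "custom" for r in self.reactions)


def validate_network(net: ReactionNetwork) -> list[str]:
    """Check all structural invariants; return diagnostics (empty = valid).

    Diagnostics name the offending element; nothing is raised.
    """
    diags: list[str] = []
    seen: set[str] = set()
    for sp in net.species:
        if sp.name in seen:
            diags.append(f"duplicate species name {sp.name!r}")
        seen.add(sp.name)
        if sp.initial_amount < 0:
            diags.append(f"species {sp.name!r} has negative initial amount")
        if net.units_mode == "count" and sp.initial_amount != int(sp.initial_amount):
            diags.append(
                f"species {sp.name!r} has non-integer amount in count mode"
            )
    if net.units_mode not in ("concentration", "count"):
        diags.append(f"unknown units_mode {net.units_mode!r}")
    for j, rxn in enumerate(net.reactions):
        label = rxn.name or f"reaction[{j}]"
        for side, members in (
            ("reactant", rxn.reactants),
            ("product", rxn.products),
            ("modifier", rxn.modifiers),
        ):
            for sp, mult in members.items():
                if sp not in seen:
                    diags.append(f"{label}: unknown {side} species {sp!r}")
                if mult < 1:
                    diags.append(f"{label}: {side} {sp!r} multiplicity < 1")
        overlap = set(rxn.reactants) & set(rxn.modifiers)
        for sp in sorted(overlap):
            diags.append(f"{label}: {sp!r} is both reactant and modifier")
        law = rxn.kinetics
        if law.form == "mass_action":
            if law.rate_constant is None or not law.rate_constant > 0:
                diags.append(f"{label}: mass-action rate constant must be > 0")
        elif law.rate_expression is None:
            diags.append(f"{label}: custom law lacks a rate expression")
    return diags


def stoichiometry(net: ReactionNetwork) -> np.ndarray:
    """Net change matrix: entry (i, j) = change of species i when reaction j fires.

    Modifiers contribute zero.
    """
    idx = {name: i for i, name in enumerate(net.species_names)}
    mat = np.zeros((len(net.species), len(net.reactions)), dtype=np.int64)
    for j, rxn in enumerate(net.reactions):
        for sp, d in rxn.net_change().items():
            mat[idx[sp], j] = d
    return mat


def discretize(net: ReactionNetwork, cfg: DiscretizationConfig) -> ReactionNetwork:
    """Convert a concentration-mode network to count mode.

    Initial amounts become ``round(amount * alpha)`` (round-half-to-even);
    a mass-action rate constant of total order m (reactants plus modifiers)
    becomes ``k / alpha**(m-1)``; a custom law of rate r(c) becomes the
    propensity ``alpha * r(counts / alpha)`` (wrapped as a callable).
    """
    if net.units_mode != "concentration":
        raise ValueError("discretize expects a concentration-mode network")
    alpha = cfg.alpha  # __post_init__ rejects non-positive alpha
    species = [
        # round-half-to-even: unbiased over many species
        Species(s.name, float(int(np.rint(s.initial_amount * alpha))))
        for s in net.species
    ]
    reactions = []
    for rxn in net.reactions:
        law = rxn.kinetics
        if law.form == "mass_action":
            new_law = KineticLaw(
                "mass_action", law.rate_constant / alpha ** (rxn.order() - 1)
            )
        else:
            new_law = KineticLaw(
                "custom", rate_expression=_rescale_custom(law, alpha)
            )
        reactions.append(
            Reaction(
                dict(rxn.reactants), dict(rxn.products), dict(rxn.modifiers),
                new_law, rxn.name,
            )
        )
    return ReactionNetwork(species, reactions, "count", net.name)


def _rescale_custom(law: KineticLaw, alpha: float) -> Callable:
    def scaled(namespace: Mapping[str, float]) -> float:
        conc = {name: val / alpha for name, val in namespace.items()}
        return alpha * law.evaluate(conc)

    return scaled


# ---------------------------------------------------------------------------
# propensity evaluation (reference NumPy path; the hot loop lives in _kernel)


def propensity(
    rxn: Reaction, state: Sequence[float] | np.ndarray, species_order: Sequence[str]
) -> float:
    """Propensity of one reaction at an integer state (count mode).

    Mass action: ``k * prod C(n_i, m_i)`` over reactant species with
    multiplicity ``m_i`` (falling factorial over m!), times plain counts for
    modifiers.  Custom: the expression value; a negative value is an error.
    """
    idx = {name: i for i, name in enumerate(species_order)}
    law = rxn.kinetics
    if law.form == "custom":
        ns = {name: float(state[idx[name]]) for name in species_order}
        val = law.evaluate(ns)
        if val < 0:
            raise ValueError(
                f"custom rate of reaction {rxn.name or '?'} is negative ({val})"
            )
        return val
    a = float(law.rate_constant)
    for sp, m in rxn.reactants.items():
        n = float(state[idx[sp]])
        for h in range(m):
            a *= n - h
        a /= math.factorial(m)
    for sp, m in rxn.modifiers.items():
        a *= float(state[idx[sp]]) ** m
    return max(a, 0.0)


def propensities(net: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    """All reaction propensities at a state (species order = network order)."""
    order = net.species_names
    return np.array([propensity(r, state, order) for r in net.reactions])


def drift(net: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    """Expected instantaneous net rate of change per species: S @ a(state)."""
    return stoichiometry(net) @ propensities(net, state)


def deterministic_rhs(net: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side f(t, x) = S @ a(x) for ODE integration of the network.

    Propensity formulas are evaluated at real-valued states, so at large
    counts this is the deterministic (macroscopic) limit of the stochastic
    model.
    """
    S = stoichiometry(net)

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        return S @ propensities(net, x)

    return rhs


# ---------------------------------------------------------------------------
# quasi-deterministic conversion


class _DriftCache:
    """Shared per-network drift evaluator with a last-state cache.

    The 2*n_species resultant channels are all evaluated at the same state in
    a simulation step; caching the drift vector makes that one evaluation.
    """

    def __init__(self, net: ReactionNetwork):
        self._net = net
        self._order = net.species_names
        self._S = stoichiometry(net)
        self._key: tuple | None = None
        self._drift: np.ndarray | None = None

    def __call__(self, namespace: Mapping[str, float]) -> np.ndarray:
        key = tuple(namespace[name] for name in self._order)
        if key != self._key:
            x = np.array(key, dtype=float)
            self._drift = self._S @ propensities(self._net, x)
            self._key = key
        return self._drift


def to_quasi_deterministic(net: ReactionNetwork) -> ReactionNetwork:
    """Combine production and consumption of each species into one resultant
    rate, simulated as a +1 channel with propensity max(r_i, 0) and a -1
    channel with propensity max(-r_i, 0), where r_i is the species' net drift
    in the source network.

    The expected instantaneous drift of every species is identical to the
    source network at every state; the intrinsic noise is far lower because
    opposing elemental fluxes no longer fire as separate events.
    """
    if net.units_mode != "count":
        raise ValueError("quasi-deterministic conversion expects count mode")
    cache = _DriftCache(net)
    reactions: list[Reaction] = []
    for i, sp in enumerate(net.species):

        def birth(ns, i=i):
            return max(float(cache(ns)[i]), 0.0)

        def death(ns, i=i):
            return max(-float(cache(ns)[i]), 0.0)

        reactions.append(
            Reaction(
                products={sp.name: 1},
                kinetics=KineticLaw("custom", rate_expression=birth),
                name=f"qd_birth_{sp.name}",
            )
        )
        reactions.append(
            Reaction(
                reactants={sp.name: 1},
                kinetics=KineticLaw("custom", rate_expression=death),
                name=f"qd_death_{sp.name}",
            )
        )
    return ReactionNetwork(
        [Species(s.name, s.initial_amount) for s in net.species],
        reactions,
        "count",
        (net.name + "_qd") if net.name else "qd",
    )
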