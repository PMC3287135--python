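"""Built-in model library: stochastic oscillators and a coupled test system.

The oscillator is a mass-action activator-substrate (Brusselator-type)
limit-cycle circuit::

    0 -> X            inflow a
    X -> Y            conversion b   (feedback strength)
    2X + Y -> 3X      autocatalytic recovery of X from the substrate pool
    X -> 0            degradation d

In the deterministic limit it oscillates for b > 1 + a**2 (at d = 1); the
period is set by measuring the dimensionless limit cycle with an ODE
integration at build time and rescaling every rate constant so the cycle
matches ``target_period``.  ``count_scale`` sets the molecule numbers (X
swings over roughly 0.5-2.5 times ``count_scale``), hence the intrinsic
noise level.  Additional species beyond the core pair are passive readouts
driven catalytically by X.

``standard_fixture`` assembles the three-subsystem test case used throughout:
a slow oscillator (period 500 min, dominant mode ~0.002 cycles/min), a fast
oscillator (period 100 min, ~0.01 cycles/min — a factor 5 apart, mirroring
two signalling pathways with well separated characteristic frequencies), and
a six-species linear production cascade standing in for the downstream
pathway they both perturb.  Each oscillator couples into the cascade at a
different entry point through a catalytic production reaction whose rate
constant is scaled by the coupling-strength multiplier (0, 1, 2 or 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .network import KineticLaw, Reaction, ReactionNetwork, Species, validate_network

__all__ = [
    "OscillatorSpec",
    "CouplingSpec",
    "make_oscillator",
    "make_cascade",
    "couple",
    "union",
    "standard_fixture",
    "StandardFixture",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """Parameters of the oscillator builder (dimensionless except the period).

    ``feedback_strength`` is the conversion rate b; oscillation requires
    b > 1 + inflow**2 when degradation is 1.  ``degradation_rates`` gives the
    dimensionless degradation of X followed by any readout species.
    """

    n_species: int = 2
    feedback_strength: float = 2.5
    degradation_rates: tuple[float, ...] = (1.0,)
    target_period: float = 100.0
    inflow: float = 1.0
    count_scale: int = 50

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least the activator-substrate pair")
        if self.feedback_strength <= 0 or self.target_period <= 0:
            raise ValueError("feedback_strength and target_period must be positive")
        if any(d <= 0 for d in self.degradation_rates):
            raise ValueError("degradation rates must be positive")


_period_cache: dict[tuple[float, float, float], float] = {}


def _dimensionless_period(a: float, b: float, d: float) -> float:
    """Limit-cycle period of x' = a - (b+d)x + x^2 y, y' = bx - x^2 y."""
    key = (a, b, d)
    if key in _period_cache:
        return _period_cache[key]

    def rhs(_t, z):
        x, y = z
        return [a - (b + d) * x + x * x * y, b * x - x * x * y]

    # start off the fixed point so the transient relaxes onto the cycle
    sol = solve_ivp(
        rhs, [0.0, 400.0], [1.3 * a, 0.7 * b / a],
        dense_output=True, rtol=1e-8, atol=1e-8, max_step=0.1,
    )
    t = np.linspace(200.0, 400.0, 40_000)
    x = sol.sol(t)[0]
    peaks, _ = find_peaks(x, height=float(x.mean()))
    if len(peaks) < 3 or np.ptp(x) < 1e-6 * max(abs(x).max(), 1.0):
        raise ValueError(
            f"oscillator spec (a={a}, b={b}, d={d}) does not sustain oscillation"
        )
    period = float(np.diff(t[peaks]).mean())
    _period_cache[key] = period
    return period


def make_oscillator(spec: OscillatorSpec, name_prefix: str = "osc") -> ReactionNetwork:
    """Build a count-mode oscillator network with the requested period.

    Species are named ``{prefix}_X`` (activator), ``{prefix}_Y`` (substrate)
    and ``{prefix}_R1..`` for readouts.  Building twice from the same spec
    yields identical networks.
    """
    a = spec.inflow
    b = spec.feedback_strength
    d = spec.degradation_rates[0]
    omega = spec.count_scale
    lam = _dimensionless_period(a, b, d) / spec.target_period
    X = f"{name_prefix}_X"
    Y = f"{name_prefix}_Y"
    species = [
        Species(X, float(round(1.3 * a * omega))),
        Species(Y, float(round(0.7 * (b / a) * omega))),
    ]
    reactions = [
        Reaction({}, {X: 1}, {}, KineticLaw("mass_action", a * omega * lam),
                 name=f"{name_prefix}_inflow"),
        Reaction({X: 1}, {Y: 1}, {}, KineticLaw("mass_action", b * lam),
                 name=f"{name_prefix}_convert"),
        Reaction({X: 2, Y: 1}, {X: 3}, {},
                 KineticLaw("mass_action", 2.0 * lam / omega**2),
                 name=f"{name_prefix}_autocat"),
        Reaction({X: 1}, {}, {}, KineticLaw("mass_action", d * lam),
                 name=f"{name_prefix}_decay"),
    ]
    # passive readout chain driven by X
    prev = X
    for i in range(spec.n_species - 2):
        name = f"{name_prefix}_R{i + 1}"
        deg = spec.degradation_rates[min(i + 1, len(spec.degradation_rates) - 1)]
        species.append(Species(name, float(omega)))
        reactions.append(
            Reaction({}, {name: 1}, {prev: 1},
                     KineticLaw("mass_action", deg * lam),
                     name=f"{name_prefix}_make_R{i + 1}")
        )
        reactions.append(
            Reaction({name: 1}, {}, {}, KineticLaw("mass_action", deg * lam * a),
                     name=f"{name_prefix}_decay_R{i + 1}")
        )
        prev = name
    net = ReactionNetwork(species, reactions, "count", name_prefix)
    diags = validate_network(net)
    if diags:  # pragma: no cover - builder bug guard
        raise AssertionError("oscillator builder produced invalid network: " + "; ".join(diags))
    return net


@dataclass(frozen=True)
class CouplingSpec:
    """Catalytic coupling from a source species into target reactions.

    ``reactions`` are the coupling channels (typically one catalytic
    production reaction with the source as modifier); the ``multiplier``
    scales only their rate constants, so multiplier 0 is an exact isolation
    limit and 1x/2x/10x sweep the coupling strength.
    """

    source: str
    reactions: tuple[Reaction, ...]
    multiplier: float = 1.0


def union(net_a: ReactionNetwork, net_b: ReactionNetwork,
          name: str = "") -> ReactionNetwork:
    """Disjoint union of two networks; species namespaces must not collide."""
    clash = set(net_a.species_names) & set(net_b.species_names)
    if clash:
        raise ValueError(f"species namespace collision: {sorted(clash)}")
    return ReactionNetwork(
        list(net_a.species) + list(net_b.species),
        list(net_a.reactions) + list(net_b.reactions),
        "count",
        name or f"{net_a.name}+{net_b.name}",
    )


def couple(
    net_a: ReactionNetwork,
    net_b: ReactionNetwork,
    coupling: CouplingSpec | Sequence[CouplingSpec],
) -> ReactionNetwork:
    """Union of two networks plus coupling reactions scaled by the multiplier."""
    specs = [coupling] if isinstance(coupling, CouplingSpec) else list(coupling)
    net = union(net_a, net_b)
    for cspec in specs:
        if cspec.source not in net.species_names:
            raise ValueError(f"coupling source {cspec.source!r} not in union network")
        if cspec.multiplier == 0:
            # zero-strength coupling channels never fire; omitting them keeps
            # the network identical to the plain union (exact isolation limit)
            continue
        for rxn in cspec.reactions:
            law = rxn.kinetics
            if law.form != "mass_action":
                raise ValueError("coupling reactions must be mass action")
            scaled = KineticLaw("mass_action", law.rate_constant * cspec.multiplier)
            net.reactions.append(
                Reaction(dict(rxn.reactants), dict(rxn.products),
                         dict(rxn.modifiers), scaled, rxn.name)
            )
    diags = validate_network(net)
    if diags:
        raise ValueError("coupled network invalid: " + "; ".join(diags))
    return net


# --- the standard three-subsystem fixture -----------------------------------

_CASCADE_DEGRADATION = (0.05, 0.01, 0.05, 0.005, 0.02, 0.05)  # per min
_CASCADE_BASAL = {"C1": 2.5, "C2": 0.5}  # molecules per min
_CASCADE_STAGE_RATES = (0.01, 0.05, 0.005, 0.02, 0.05)  # Ci -> Ci + C(i+1)
_CASCADE_STEADY = (50.0, 100.0, 100.0, 100.0, 100.0, 100.0)
_COUPLING_RATE_SLOW = 0.05  # slow_X catalyses C1 production
_COUPLING_RATE_FAST = 0.02  # fast_X catalyses C2 production

SLOW_SPEC = OscillatorSpec(target_period=500.0, count_scale=50)
FAST_SPEC = OscillatorSpec(target_period=100.0, count_scale=50)


def make_cascade(name: str = "cascade") -> ReactionNetwork:
    """Six-species linear production cascade C1 -> ... -> C6.

    C1 and C2 have basal inflow; each stage catalyses production of the next;
    degradation rates are deliberately heterogeneous so the stages filter the
    oscillatory drive differently (corner frequencies straddle both
    oscillators' characteristic frequencies).  Initial amounts are the
    uncoupled steady state.
    """
    species = [Species(f"C{i + 1}", _CASCADE_STEADY[i]) for i in range(6)]
    reactions = []
    for sp, k in _CASCADE_BASAL.items():
        reactions.append(Reaction({}, {sp: 1}, {}, KineticLaw("mass_action", k),
                                  name=f"basal_{sp}"))
    for i, k in enumerate(_CASCADE_STAGE_RATES):
        src, dst = f"C{i + 1}", f"C{i + 2}"
        reactions.append(Reaction({}, {dst: 1}, {src: 1},
                                  KineticLaw("mass_action", k),
                                  name=f"stage_{src}_{dst}"))
    for i, d in enumerate(_CASCADE_DEGRADATION):
        sp = f"C{i + 1}"
        reactions.append(Reaction({sp: 1}, {}, {}, KineticLaw("mass_action", d),
                                  name=f"decay_{sp}"))
    return ReactionNetwork(species, reactions, "count", name)


@dataclass
class StandardFixture:
    """The versioned three-subsystem test case (see :func:`standard_fixture`)."""

    slow: ReactionNetwork
    fast: ReactionNetwork
    cascade: ReactionNetwork
    coupling_slow: CouplingSpec
    coupling_fast: CouplingSpec
    version: str = "1"

    def oscillators(self) -> ReactionNetwork:
        return union(self.slow, self.fast, name="oscillators")

    def uncoupled(self) -> ReactionNetwork:
        """Union of all three subsystems with no coupling reactions."""
        net = union(self.oscillators(), self.cascade, name="fixture_uncoupled")
        return net

    def coupled(self, mult_slow: float = 1.0, mult_fast: float = 1.0) -> ReactionNetwork:
        """Full system with coupling strengths (0 disables a coupling exactly)."""
        specs = [
            replace(self.coupling_slow, multiplier=mult_slow),
            replace(self.coupling_fast, multiplier=mult_fast),
        ]
        net = couple(self.oscillators(), self.cascade, specs)
        net.name = f"fixture_coupled_{mult_slow:g}x_{mult_fast:g}x"
        return net

    @property
    def cascade_species(self) -> list[str]:
        return self.cascade.species_names


def standard_fixture() -> StandardFixture:
    """Deterministic, versioned fixture: two oscillators and a cascade.

    The slow oscillator (period 500 min) couples into C1, the fast one
    (period 100 min) into C2, so the cascade offers species at graph
    distances 1..6 and 1..5 from the two coupling points respectively.
    """
    slow = make_oscillator(SLOW_SPEC, "slow")
    fast = make_oscillator(FAST_SPEC, "fast")
    cascade = make_cascade()
    coupling_slow = CouplingSpec(
        "slow_X",
        (Reaction({}, {"C1": 1}, {"slow_X": 1},
                  KineticLaw("mass_action", _COUPLING_RATE_SLOW),
                  name="couple_slow_C1"),),
    )
    coupling_fast = CouplingSpec(
        "fast_X",
        (Reaction({}, {"C2": 1}, {"fast_X": 1},
                  KineticLaw("mass_action", _COUPLING_RATE_FAST),
                  name="couple_fast_C2"),),
    )
    return StandardFixture(slow, fast, cascade, coupling_slow, coupling_fast)
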