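"""Exact stochastic simulation (Gillespie direct method).

Each trajectory is a full event record: strictly increasing times starting at
0 and the integer state after every reaction firing.  Waiting times are
exponential in the total propensity and the firing channel is drawn
categorically, so the sampled process is exactly the continuous-time Markov
jump process defined by the network's propensities.

Pure mass-action networks run through a numba-compiled kernel; networks with
custom kinetic laws (including quasi-deterministic conversions) run through an
equivalent pure-Python loop.  Per-run seeds in :func:`simulate_ensemble` are
derived from ``(base_seed, run_index)`` via :class:`numpy.random.SeedSequence`
so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .network import ReactionNetwork, stoichiometry, validate_network

__all__ = [
    "SimConfig",
    "Trajectory",
    "simulate",
    "simulate_ensemble",
    "iter_ensemble",
    "derive_seed",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

_TERM_REASONS = {
    _kernel.TERM_TMAX: "t_max reached",
    _kernel.TERM_EXHAUSTED: "no reaction possible",
    _kernel.TERM_EVENT_CAP: "event cap reached",
}


@dataclass
class SimConfig:
    """Simulation window and seeding.

    ``record`` is either ``"all_events"`` (default; required by the
    last-value resampler) or a sequence of species names to keep as columns.
    """

    t_max: float
    seed: int = 0
    record: str | Sequence[str] = "all_events"
    max_events: int = 50_000_000

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")


@dataclass
class Trajectory:
    """One stochastic run: event times and the state after each event."""

    times: np.ndarray
    states: np.ndarray  # shape (n_events + 1, n_species)
    species_order: list[str]
    seed: int
    terminated_reason: str = "t_max reached"

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.species_order.index(species)]


class _Compiled:
    """Flattened mass-action arrays for the numba kernel, cached per network."""

    def __init__(self, net: ReactionNetwork):
        idx = {name: i for i, name in enumerate(net.species_names)}
        rates, r_i, r_m, r_p = [], [], [], [0]
        m_i, m_m, m_p = [], [], [0]
        S = stoichiometry(net)
        s_i, s_d, s_p = [], [], [0]
        for j, rxn in enumerate(net.reactions):
            rates.append(float(rxn.kinetics.rate_constant))
            for sp, mult in rxn.reactants.items():
                r_i.append(idx[sp])
                r_m.append(mult)
            r_p.append(len(r_i))
            for sp, mult in rxn.modifiers.items():
                m_i.append(idx[sp])
                m_m.append(mult)
            m_p.append(len(m_i))
            rows = np.nonzero(S[:, j])[0]
            s_i.extend(int(r) for r in rows)
            s_d.extend(int(S[r, j]) for r in rows)
            s_p.append(len(s_i))
        self.rates = np.asarray(rates, dtype=np.float64)
        self.react_idx = np.asarray(r_i, dtype=np.int64)
        self.react_mult = np.asarray(r_m, dtype=np.int64)
        self.react_ptr = np.asarray(r_p, dtype=np.int64)
        self.mod_idx = np.asarray(m_i, dtype=np.int64)
        self.mod_mult = np.asarray(m_m, dtype=np.int64)
        self.mod_ptr = np.asarray(m_p, dtype=np.int64)
        self.st_idx = np.asarray(s_i, dtype=np.int64)
        self.st_delta = np.asarray(s_d, dtype=np.int64)
        self.st_ptr = np.asarray(s_p, dtype=np.int64)


def _compiled(net: ReactionNetwork) -> _Compiled:
    comp = net.__dict__.get("_oscspec_compiled")
    if comp is None:
        comp = _Compiled(net)
        net.__dict__["_oscspec_compiled"] = comp
    return comp


def derive_seed(base_seed: int, run_index: int) -> int:
    """Deterministic, order-independent per-run seed below 2**31."""
    return int(
        np.random.SeedSequence([int(base_seed), int(run_index)]).generate_state(1)[0]
        % (2**31)
    )


def simulate(net: ReactionNetwork, cfg: SimConfig) -> Trajectory:
    """Run one exact direct-method trajectory, reproducible from ``cfg.seed``."""
    diags = validate_network(net)
    if diags:
        raise ValueError("invalid network: " + "; ".join(diags))
    if net.units_mode != "count":
        raise ValueError("simulation requires a count-mode network (discretize first)")
    x0 = net.initial_state()
    if net.has_custom_laws():
        times, states, term = _run_generic(net, x0, cfg)
    else:
        comp = _compiled(net)
        times, states, term = _kernel.run_direct(
            x0, float(cfg.t_max), int(cfg.seed) % (2**32),
            comp.rates,
            comp.react_idx, comp.react_mult, comp.react_ptr,
            comp.mod_idx, comp.mod_mult, comp.mod_ptr,
            comp.st_idx, comp.st_delta, comp.st_ptr,
            int(cfg.max_events),
        )
    if term == _kernel.TERM_NONFINITE:
        raise ArithmeticError(
            "non-finite total propensity; last state: "
            + repr(dict(zip(net.species_names, states[-1])))
        )
    order = list(net.species_names)
    if cfg.record != "all_events":
        keep = [order.index(s) for s in cfg.record]
        states = states[:, keep]
        order = list(cfg.record)
    return Trajectory(times, states, order, cfg.seed, _TERM_REASONS[term])


def _run_generic(net: ReactionNetwork, x0: np.ndarray, cfg: SimConfig):
    """Python direct-method loop for networks with custom kinetic laws."""
    from .network import propensity

    rng = np.random.default_rng(cfg.seed)
    order = net.species_names
    S = stoichiometry(net)
    cols = [np.nonzero(S[:, j])[0] for j in range(S.shape[1])]
    deltas = [S[c, j] for j, c in enumerate(cols)]
    x = x0.astype(np.int64).copy()
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    term = _kernel.TERM_TMAX
    n_rxn = len(net.reactions)
    while True:
        ns = dict(zip(order, (float(v) for v in x)))
        a = np.empty(n_rxn)
        for j, rxn in enumerate(net.reactions):
            if rxn.kinetics.form == "custom":
                val = rxn.kinetics.evaluate(ns)
                if val < 0:
                    raise ValueError(
                        f"custom rate of reaction {rxn.name or j} is negative "
                        f"({val}) at state {ns}"
                    )
                a[j] = val
            else:
                a[j] = propensity(rxn, x, order)
        a0 = float(a.sum())
        if not np.isfinite(a0):
            term = _kernel.TERM_NONFINITE
            break
        if a0 <= 0.0:
            term = _kernel.TERM_EXHAUSTED
            break
        t += rng.exponential(1.0 / a0)
        if t > cfg.t_max:
            term = _kernel.TERM_TMAX
            break
        u = rng.random() * a0
        c = 0.0
        j_sel = n_rxn - 1
        for j in range(n_rxn):
            c += a[j]
            if u < c:
                j_sel = j
                break
        x[cols[j_sel]] += deltas[j_sel]
        if (x < 0).any():
            raise ValueError(
                f"reaction {net.reactions[j_sel].name or j_sel} drove a count "
                "negative (custom law inconsistent with stoichiometry)"
            )
        times.append(t)
        states.append(x.copy())
        if len(times) - 1 >= cfg.max_events:
            term = _kernel.TERM_EVENT_CAP
            break
    return np.asarray(times), np.asarray(states), term


def iter_ensemble(
    net: ReactionNetwork, cfg: SimConfig, K: int, base_seed: int
) -> Iterator[Trajectory]:
    """Yield K independent trajectories one at a time (memory-friendly)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    for i in range(K):
        run_cfg = SimConfig(cfg.t_max, derive_seed(base_seed, i), cfg.record,
                            cfg.max_events)
        try:
            yield simulate(net, run_cfg)
        except Exception as err:
            raise RuntimeError(f"ensemble run {i} failed: {err}") from err


def simulate_ensemble(
    net: ReactionNetwork, cfg: SimConfig, K: int, base_seed: int
) -> list[Trajectory]:
    """K independent runs with seeds derived from (base_seed, run index)."""
    return list(iter_ensemble(net, cfg, K, base_seed))


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Write one row per event: time, then one column per species."""
    df = pd.DataFrame(traj.states, columns=traj.species_order)
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def trajectory_from_csv(path: str | Path, seed: int = -1) -> Trajectory:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    species = [c for c in df.columns if c != "time"]
    return Trajectory(
        df["time"].to_numpy(float),
        df[species].to_numpy(np.int64),
        species,
        seed,
        "t_max reached",
    )


def network_hash(net: ReactionNetwork) -> str:
    """Stable content hash of a network (for run manifests)."""
    from .netio import format_network

    try:
        text = format_network(net)
    except ValueError:
        text = repr(net)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
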