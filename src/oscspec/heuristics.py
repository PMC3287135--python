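"""Signed influence graphs and topology-based crosstalk heuristics.

The influence graph abstracts a reaction network into signed directed edges:
A -> B positive when A is a substrate or enzyme for a reaction producing B
(more A, more B made); A -> B negative when B is consumed in a reaction in
which A is a substrate or enzyme (more A, more B consumed).  Self-edges are
excluded.

Two topology heuristics predict how strongly a perturbation at a source
species should propagate: the minimum directed distance (number of steps,
signs ignored) and a weighted proximity summing 1/length over all simple
directed paths up to a cutoff.  A signed variant multiplies each path's
contribution by the product of its edge signs.  ``evaluate_heuristic`` scores
any of these against a measured per-species distance table by ordinary
least-squares R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .network import ReactionNetwork

__all__ = [
    "build_influence_graph",
    "min_distance",
    "weighted_proximity",
    "signed_proximity",
    "evaluate_heuristic",
    "HeuristicEvaluation",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class HeuristicEvaluation:
    """Least-squares fit of measured D against a heuristic score."""

    r_squared: float
    slope: float
    intercept: float
    species: list[str]


def build_influence_graph(net: ReactionNetwork) -> nx.DiGraph:
    """Signed influence graph of a network.

    Each edge carries a ``signs`` attribute, a frozenset drawn from
    ``{+1, -1}``; a pair of opposite influences between the same species is a
    single edge with both signs.  For every reaction, every reactant or
    modifier influences every net-produced species positively and every
    net-consumed species negatively; self-influences are dropped.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.species_names)
    signs: dict[tuple[str, str], set[int]] = {}
    for rxn in net.reactions:
        influencers = set(rxn.reactants) | set(rxn.modifiers)
        delta = rxn.net_change()
        produced = [sp for sp, d in delta.items() if d > 0]
        consumed = [sp for sp, d in delta.items() if d < 0]
        for a in influencers:
            for b in produced:
                if a != b:
                    signs.setdefault((a, b), set()).add(+1)
            for b in consumed:
                if a != b:
                    signs.setdefault((a, b), set()).add(-1)
    for (a, b), s in signs.items():
        g.add_edge(a, b, signs=frozenset(s))
    return g


def min_distance(g: nx.DiGraph, source: str) -> dict[str, int | None]:
    """Shortest directed path length (edges) from source, signs ignored.

    Unreachable species map to ``None`` — never 0, which is reserved for the
    source itself.
    """
    if source not in g:
        raise KeyError(f"unknown source species {source!r}")
    lengths = nx.single_source_shortest_path_length(g, source)
    return {node: lengths.get(node) for node in g.nodes}


def _simple_paths(g: nx.DiGraph, source: str, max_len: int):
    for target in g.nodes:
        if target == source:
            continue
        for path in nx.all_simple_paths(g, source, target, cutoff=max_len):
            yield target, path


def weighted_proximity(
    g: nx.DiGraph, source: str, max_len: int | None = None
) -> dict[str, float]:
    """Sum of 1/length over all simple directed paths from source, per species.

    ``max_len`` caps the path length in edges (default: number of nodes, i.e.
    effectively unbounded for simple paths).  Signs are ignored.  Species with
    no path score 0.
    """
    if source not in g:
        raise KeyError(f"unknown source species {source!r}")
    if max_len is None:
        max_len = g.number_of_nodes()
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = {node: 0.0 for node in g.nodes if node != source}
    for target, path in _simple_paths(g, source, max_len):
        out[target] += 1.0 / (len(path) - 1)
    return out


def signed_proximity(
    g: nx.DiGraph, source: str, max_len: int | None = None
) -> dict[str, float]:
    """Sign-aware proximity: each path contributes sign(path)/length.

    A path's sign is the product of its edge signs; an edge carrying both a
    positive and a negative influence contributes the sum of its signs (zero),
    so antagonistic parallel influences cancel.
    """
    if source not in g:
        raise KeyError(f"unknown source species {source!r}")
    if max_len is None:
        max_len = g.number_of_nodes()
    out = {node: 0.0 for node in g.nodes if node != source}
    for target, path in _simple_paths(g, source, max_len):
        sign = 1.0
        for a, b in zip(path[:-1], path[1:]):
            sign *= sum(g.edges[a, b]["signs"])
        out[target] += sign / (len(path) - 1)
    return out


def evaluate_heuristic(
    scores: Mapping[str, float],
    measured_D: Mapping[str, float],
    include_unreachable: bool = False,
) -> HeuristicEvaluation:
    """R² of an ordinary least-squares fit of measured D on heuristic score.

    Species present in both tables with a finite score enter the fit;
    unreachable species (score ``None`` or non-finite) are excluded unless
    ``include_unreachable``, in which case they enter with score 0.  With an
    intercept, R² equals the squared Pearson correlation, so the regression
    direction does not affect it.  A constant score explains nothing: R² = 0.
    """
    xs, ys, used = [], [], []
    for name, score in scores.items():
        if name not in measured_D:
            continue
        if score is None or not math.isfinite(score):
            if not include_unreachable:
                continue
            score = 0.0
        xs.append(float(score))
        ys.append(float(measured_D[name]))
        used.append(name)
    if len(xs) < 3:
        raise ValueError(f"need at least 3 species with finite scores, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return HeuristicEvaluation(0.0, 0.0, float(y.mean()), used)
    fit = stats.linregress(x, y)
    return HeuristicEvaluation(
        float(fit.rvalue**2), float(fit.slope), float(fit.intercept), used
    )


def write_edge_list(g: nx.DiGraph, path: str | Path) -> None:
    """CSV edge list with one row per (source, target, sign)."""
    lines = ["source,target,sign"]
    for a, b, data in g.edges(data=True):
        for sign in sorted(data["signs"], reverse=True):
            lines.append(f"{a},{b},{sign:+d}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    """GraphML export; the sign set is flattened to a '+-'-style string."""
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for a, b, data in g.edges(data=True):
        h.add_edge(a, b, signs="".join(
            "+" if s > 0 else "-" for s in sorted(data["signs"], reverse=True)
        ))
    nx.write_graphml(h, str(path))
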