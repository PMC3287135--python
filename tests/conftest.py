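"""Shared fixtures.

The crosstalk tables are expensive (six ensembles of 100 full-system runs),
so they are computed once per session and shared by the model-library,
heuristics and acceptance tests.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pytest

import oscspec as osc

# study conditions: the sampling grid and ensemble size used throughout
SAMPLING = osc.SamplingConfig(N=4000, dt=1.0)
SIM = osc.SimConfig(t_max=SAMPLING.window)
K_RUNS = 100
# resolution in D achievable with 100 runs; doubles as the null floor
NULL_FLOOR = 0.05


@pytest.fixture(scope="session")
def fixture3():
    return osc.standard_fixture()


@dataclass
class CrosstalkTables:
    """Per-species D of each coupling condition against the uncoupled system."""

    null: dict[str, float]          # uncoupled vs independent uncoupled
    mult0: dict[str, float]         # coupling present but multiplier 0
    slow_only: dict[str, float]     # slow oscillator -> C1, strength 1
    fast_only: dict[str, float]     # fast oscillator -> C2, strength 1
    joint: dict[str, float]         # both couplings, strength 1
    joint_runtime_s: float          # wall time of the joint 100-run ensemble


def _averages(net, species, base_seed):
    return osc.procedure_A(net, SIM, SAMPLING, K_RUNS, base_seed, species)


@pytest.fixture(scope="session")
def crosstalk(fixture3) -> CrosstalkTables:
    fx = fixture3
    species = fx.cascade_species
    uncoupled = fx.uncoupled()
    ref = _averages(uncoupled, species, base_seed=101)
    ref2 = _averages(uncoupled, species, base_seed=102)
    c00 = _averages(fx.coupled(0, 0), species, base_seed=103)
    slow = _averages(fx.coupled(1, 0), species, base_seed=104)
    fast = _averages(fx.coupled(0, 1), species, base_seed=105)
    t0 = time.perf_counter()
    joint = _averages(fx.coupled(1, 1), species, base_seed=106)
    joint_s = time.perf_counter() - t0

    def table(avgs):
        return {
            name: osc.ks_distance(avgs[name], ref[name]).D for name in species
        }

    return CrosstalkTables(
        null=table(ref2),
        mult0=table(c00),
        slow_only=table(slow),
        fast_only=table(fast),
        joint=table(joint),
        joint_runtime_s=joint_s,
    )
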