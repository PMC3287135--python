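"""Numba-compiled inner loop of the Gillespie direct method.

Reactions are passed as flat CSR-style arrays so the kernel stays free of
Python objects.  Reaction selection uses a cumulative-sum search with strict
inequality (``u < c``), so appending zero-propensity channels never changes
which reaction fires for a given random stream — coupling reactions with a
zero strength multiplier leave trajectories bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# termination codes
TERM_TMAX = 0
TERM_EXHAUSTED = 1
TERM_NONFINITE = 2
TERM_EVENT_CAP = 3


@njit(cache=True)
def run_direct(
    x0,
    t_max,
    seed,
    rates,
    react_idx,
    react_mult,
    react_ptr,
    mod_idx,
    mod_mult,
    mod_ptr,
    st_idx,
    st_delta,
    st_ptr,
    max_events,
):  # pragma: no cover - exercised via ssa.simulate
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    n_sp = x0.shape[0]
    cap = 1024
    times = np.empty(cap, np.float64)
    states = np.empty((cap, n_sp), np.int64)
    times[0] = 0.0
    states[0, :] = x0
    x = x0.copy()
    a = np.empty(n_rxn, np.float64)
    ne = 0
    t = 0.0
    term = TERM_TMAX
    while True:
        a0 = 0.0
        for j in range(n_rxn):
            p = rates[j]
            for q in range(react_ptr[j], react_ptr[j + 1]):
                n = x[react_idx[q]]
                m = react_mult[q]
                fact = 1.0
                for h in range(m):
                    p *= n - h
                    fact *= h + 1
                p /= fact
            for q in range(mod_ptr[j], mod_ptr[j + 1]):
                n = x[mod_idx[q]]
                for h in range(mod_mult[q]):
                    p *= n
            if p < 0.0:
                p = 0.0
            a[j] = p
            a0 += p
        if not np.isfinite(a0):
            term = TERM_NONFINITE
            break
        if a0 <= 0.0:
            term = TERM_EXHAUSTED
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_max:
            term = TERM_TMAX
            break
        u = np.random.random() * a0
        c = 0.0
        j_sel = n_rxn - 1
        for j in range(n_rxn):
            c += a[j]
            if u < c:
                j_sel = j
                break
        for q in range(st_ptr[j_sel], st_ptr[j_sel + 1]):
            x[st_idx[q]] += st_delta[q]
        ne += 1
        if ne >= cap:
            new_cap = cap * 2
            t2 = np.empty(new_cap, np.float64)
            t2[:cap] = times
            times = t2
            s2 = np.empty((new_cap, n_sp), np.int64)
            s2[:cap, :] = states
            states = s2
            cap = new_cap
        times[ne] = t
        states[ne, :] = x
        if ne >= max_events:
            term = TERM_EVENT_CAP
            break
    return times[: ne + 1], states[: ne + 1], term
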