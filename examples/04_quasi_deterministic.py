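"""Quasi-deterministic conversion: same drift, far less noise.

Replaces the oscillator's four elemental reaction channels by one resultant
birth/death channel pair per species.  The expected instantaneous drift is
identical to the elemental model at every state (checked below), but
opposing fluxes no longer fire as separate events, so the intrinsic noise
nearly vanishes and the trajectory tracks the deterministic (ODE) limit.
"""

import numpy as np

import oscspec as osc
from oscspec.network import drift

net = osc.make_oscillator(osc.OscillatorSpec(target_period=100.0,
                                             count_scale=2000), "osc")
qd = osc.to_quasi_deterministic(net)

rng = np.random.default_rng(0)
worst = max(
    np.max(np.abs(drift(net, x) - drift(qd, x))
           / np.maximum(np.abs(drift(net, x)), 1e-300))
    for x in rng.integers(0, 5000, size=(200, 2))
)
print(f"max relative drift mismatch over 200 random states: {worst:.2e}")

sampling = osc.SamplingConfig(N=400, dt=1.0)
sim = osc.SimConfig(t_max=sampling.window, seed=5)
for label, model in (("elemental ", net), ("quasi-det.", qd)):
    traj = osc.simulate(model, sim)
    spec = osc.amplitude_spectrum(osc.resample(traj, sampling, "osc_X"))
    # the flat amplitude floor far above the 0.01 cycles/min oscillation is
    # pure intrinsic noise
    floor = spec.amplitudes[spec.frequencies > 0.1].mean()
    print(f"{label} run: {traj.n_events:7d} events, "
          f"high-frequency noise floor = {floor:8.1f}")
print("The quasi-deterministic trace keeps the oscillation but runs on far")
print("fewer, net events and a several-fold lower noise floor: stochasticity")
print("itself becomes a measurable, comparable ingredient of model behaviour.")
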