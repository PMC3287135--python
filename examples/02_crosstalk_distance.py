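"""Crosstalk measured as a spectral distance (Procedure B).

Couples the slow oscillator into a six-species cascade and compares the
coupled and uncoupled systems per species with the Kolmogorov-Smirnov
distance D between their average amplitude spectra.  D ~ 0 means the
coupling leaves that species' behaviour unchanged; larger D means stronger
perturbation.  With 100 runs per side the method resolves differences in D
of about 0.05; this demo uses 20 runs per side to stay quick.
"""

import oscspec as osc

fx = osc.standard_fixture()
sampling = osc.SamplingConfig(N=4000, dt=1.0)
sim = osc.SimConfig(t_max=sampling.window)

D = osc.procedure_B(
    fx.coupled(1, 0),          # slow oscillator -> C1, coupling strength 1x
    fx.uncoupled(),
    sim,
    sampling,
    K=20,
    base_seed=7,
    species_list=fx.cascade_species,
)

print("per-species behavioural distance D (coupled vs uncoupled):")
for name, d in D.items():
    bar = "#" * int(round(d * 200))
    print(f"  {name}: {d:.3f} {bar}")
print("C1 is the directly driven species; D decays along the cascade as the")
print("slow oscillation is filtered by each stage's degradation rate.")
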