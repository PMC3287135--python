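"""Average amplitude spectrum of a stochastic oscillator (Procedure A).

Builds the built-in fast oscillator (target period 100 min), runs a small
ensemble of exact stochastic simulations, and averages the per-run DFT
amplitude spectra.  The dominant non-DC bin recovers the oscillator's
characteristic frequency; the DC bin carries the mean level and transient.
"""

import oscspec as osc

sampling = osc.SamplingConfig(N=4000, dt=1.0)   # 4000 one-minute samples
net = osc.make_oscillator(osc.OscillatorSpec(target_period=100.0), "osc")

avgs = osc.procedure_A(
    net,
    osc.SimConfig(t_max=sampling.window),
    sampling,
    K=20,                      # 20 runs: enough for a clean demo spectrum
    base_seed=1,
    species_list=["osc_X"],
)
avg = avgs["osc_X"]
cov, converged = osc.convergence_cov(avg, threshold=0.05)

print(f"frequency resolution : {sampling.resolution} cycles/min")
print(f"max observable freq  : {sampling.max_frequency} cycles/min")
print(f"dominant non-DC mode : {avg.dominant_frequency():.4f} cycles/min "
      f"(target 1/100 = 0.0100)")
print(f"peak / DC amplitude  : {avg.means[1:].max() / avg.means[0]:.3f}")
print(f"CoV criterion (<=5%) : {'met' if converged else 'not met'} at K={avg.K}")
# The dominant mode sits at the deterministic limit-cycle frequency even
# though every individual run has a randomly drifting phase - averaging
# amplitudes (not complex spectra) is what preserves it.
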