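# oscspec

Frequency-domain characterisation and comparison of stochastically simulated
biochemical reaction networks.

## The problem

Coupled signalling pathways — oscillating gene circuits such as p53/Mdm2 or
NF-κB feeding into the cell cycle — are naturally modelled as discrete
stochastic reaction networks. But stochastic simulations resist comparison:
every run is different, and the *time-domain ensemble mean* is useless for
oscillators, because runs drift out of phase and their average decays to a
flat line even when every single run oscillates forever. `oscspec`
implements a spectral alternative for systems biologists who need to ask
"did this coupling / parameter change / simplification change the model's
behaviour, and by how much, species by species?"

## The method

For each of K simulation runs (exact Gillespie direct-method SSA), each
species' irregular event trace is resampled onto a regular grid by
last-value sampling, x_n = x_t | max(t ≤ n·δt), and transformed:

    f_ω = Σ_{n=0}^{N-1} x_n e^{-2πiωn/N}          (DFT, via FFT)
    f̂_ω = |f_ω|                                   (amplitude spectrum)
    f̃_ω = (1/K) Σ_i f̂_{ω,i}                      (ensemble average)

Averaging **amplitudes** rather than complex spectra discards the incoherent
phases and preserves the oscillatory signature that time-domain averaging
destroys. Two conditions are compared per species by a discrete
Kolmogorov–Smirnov distance between their average spectra, normalised to
unit mass:

    D = max |F_1(ω) - F_2(ω)|  ∈ [0, 1]

With N samples δt apart the observation window is N·δt, the frequency
resolution (N·δt)⁻¹ and the maximum observable frequency (2·δt)⁻¹. At the
default study conditions (N = 4000, δt = 1 min, K = 100) the method resolves
differences in D of about 0.05.

The package also provides:

* a plain-text reaction dialect (`A + B -> C [k=0.1]`, optional
  `{modifiers: E}` and `rate="expr"` custom kinetics) plus optional SBML
  import, α-discretization from concentrations to molecule counts, and a
  **quasi-deterministic conversion** that collapses each species' production
  and consumption into one resultant birth/death channel with identical
  expected drift but greatly reduced intrinsic noise;
* **topology heuristics** on the signed influence graph (minimum directed
  distance and an all-simple-paths proximity weighted by 1/length, with a
  sign-aware variant), scored against measured D tables by least-squares R²;
* a **model library** of mass-action limit-cycle oscillators with tunable
  period and molecule numbers, and a standard three-subsystem fixture (slow
  oscillator → cascade ← fast oscillator) with 0×/1×/2×/10× coupling
  strengths for crosstalk experiments.

## Worked example

`examples/` contains one short script per capability. For instance,
measuring the crosstalk a slow oscillator (period 500 min) inflicts on a
six-species cascade it is coupled into:

```sh
$ python examples/02_crosstalk_distance.py
per-species behavioural distance D (coupled vs uncoupled):
  C1: 0.166 #################################
  C2: 0.047 #########
  C3: 0.064 #############
  C4: 0.017 ###
  C5: 0.038 ########
  C6: 0.045 #########
C1 is the directly driven species; D decays along the cascade as the
slow oscillation is filtered by each stage's degradation rate.
```

C1 — the species the oscillator drives directly — is strongly perturbed
(D = 0.166, far above the ≈0.05 null resolution), and the perturbation
decays non-monotonically downstream. Running the same comparison for the
*fast* oscillator's entry point shows the opposite pattern: the directly
driven species is *not* the most perturbed one, and the topology heuristics
change their ranking accordingly (`examples/03_topology_heuristics.py`):

```
perturbation source slow_X:
  min distance        R^2 = 0.437
  weighted proximity  R^2 = 0.815
perturbation source fast_X:
  min distance        R^2 = 0.382
  weighted proximity  R^2 = 0.003
```

The same analyses are available from the shell via the thin CLI
(`oscspec simulate | spectra | compare | heuristics | fixture`).

## Documentation

`docs/methods.md` describes the model assumptions, parameter choices,
numerical conventions and known limitations in detail.
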