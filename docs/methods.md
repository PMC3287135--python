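# Methods

## Scope and model class

`oscspec` analyses continuous-time Markov jump processes defined by reaction
networks: an ordered species list, reactions with mass-action or custom
kinetic laws, and explicit catalytic modifiers. Networks exist in
concentration units (mol/l) or molecule counts; all simulation happens in
count mode. Out of scope by design: compartments, events, assignment rules,
delays, tau-leaping/hybrid solvers, spatial models, and wavelet or
information-theoretic behavioural measures.

## Discretization (α)

A single constant α (l/mol) converts a concentration model to counts:
initial amounts become round(c·α) (round-half-to-even, unbiased over many
species), and a mass-action constant of total kinetic order m (reactant plus
modifier multiplicities) becomes k/α^(m-1). Custom laws r(c) become the
propensity α·r(n/α), wrapped as a callable (and therefore no longer
serialisable to the text dialect). The count-mode propensity of any
mass-action reaction evaluated at n = α·c then equals α times the
concentration-space rate, exactly for order ≤ 1 and up to terms that vanish
as α → ∞ otherwise. One deliberate divergence from naive rescaling:
homodimerisation (and higher self-orders) uses the combinatorial form
k·n(n−1)/2, the physically correct elemental propensity, rather than k·n²/…
— constant factors of up to m! relative to a k·cᵐ macroscopic convention
are absorbed into the rate constant the user writes.

## Stochastic simulation

The simulator is the plain Gillespie direct method: waiting times are
exponential in the total propensity a₀ and the firing channel is drawn
categorically with probability a_j/a₀. Any exact SSA variant samples the
same process, so no accelerated or partial-propensity variant is needed at
this problem scale. Implementation notes:

* Mass-action propensities use falling-factorial combinatorics
  (∏ C(n_i, m_i)) with modifiers entering as plain count powers; pure
  mass-action networks run through a numba-compiled kernel, networks with
  custom laws (including quasi-deterministic conversions) through an
  equivalent Python loop.
* Channel selection is a cumulative-sum search with strict inequality
  (u < Σa_j), which makes trajectories invariant under appending
  zero-propensity channels — the basis of the exact coupling-strength-zero
  isolation limit — and reproducible across platforms for a given RNG.
* Per-run seeds derive from (base_seed, run_index) through
  `numpy.random.SeedSequence`, so ensembles are reproducible and
  order-independent; the mass-action kernel seeds numba's Mersenne Twister,
  the generic path uses `numpy.random.default_rng`. The two paths are
  statistically, not bitwise, equivalent.
* Trajectories record every event (required by the last-value resampler);
  memory-sensitive pipelines stream runs one at a time via `iter_ensemble`.
  A configurable event cap (default 5·10⁷) guards against runaway models,
  and a non-finite total propensity aborts with the offending state.

## Quasi-deterministic conversion

For each species i the production and consumption kinetics of the source
network are combined into one resultant rate r_i(x) = Σ_j S_ij·a_j(x),
simulated as a +1 channel with propensity max(r_i, 0) and a −1 channel with
propensity max(−r_i, 0). The split into two clamped channels is our
resolution of the sign question the construction leaves open: it keeps all
propensities non-negative as the SSA requires while preserving the expected
instantaneous drift of every species at every state exactly (verified to
1e-12 relative in the tests). Because opposing elemental fluxes no longer
fire as separate events, intrinsic noise drops sharply; at large counts the
trajectory tracks the deterministic ODE limit (the tests demonstrate
agreement within 2% of peak amplitude over a full oscillation period at
counts of order 10⁴, the scale chosen so that the residual √n shot noise
sits comfortably below that band). At states where production exactly
balances consumption all channel propensities vanish and the model freezes —
a known, documented property of the construction rather than a defect.

## Sampling and spectra

Irregular event traces are resampled by last-value (LOCF) sampling at
t_n = n·δt, n = 0..N−1; a trajectory that terminates early (absorbing
state) carries its final value forward, consistent with the sampling rule.
The DFT uses the standard e^(−2πiωn/N) kernel and is applied to the raw
samples — no windowing, detrending or normalisation — because the DC bin
and the low-frequency transient are part of the behavioural signature being
compared. One-sided spectra (bins 0..⌊N/2⌋) are retained; real input makes
the mirrored bins redundant and keeping them would only double-count mass
in the K-S comparison.

Ensemble averages are term-wise arithmetic means of amplitude spectra,
accumulated by Welford's algorithm so that ensembles can be extended run by
run while agreeing with the batch mean to floating-point accuracy. The
per-bin second moments feed the convergence criterion: the coefficient of
variation of each bin mean, (sample std/√K)/mean, must fall below a
threshold (default 5%) on every bin whose mean exceeds a floor (default 1%
of the largest bin — near-empty bins have irrelevant relative error). On
stochastic ensembles this CoV decays as K^(−1/2), which the tests verify by
regression. The sequential-hypothesis-test stopping rule sometimes used for
expensive models is intentionally not implemented; the CoV criterion is the
supported stopping rule.

## The behavioural distance D

Each average amplitude spectrum is normalised to unit sum (the definition
of D requires probability distributions; raw amplitude scales would make D
units-dependent), cumulative sums are formed over ascending frequency, and
D = max|F₁−F₂|. D is symmetric, zero for identical spectra, and bounded in
[0, 1]. Both spectra must share the (N, δt) grid and have positive total
mass. At the default study conditions (N = 4000, δt = 1 min — resolution
0.00025 cycles/min, maximum frequency 0.5 cycles/min — and K = 100 runs per
condition) two independent ensembles of the same model yield D well below
0.05, which is therefore used throughout as the null floor: differences
below it are not resolved, differences above it are real.

## Influence graph and topology heuristics

Edges are derived reaction-wise: every reactant or modifier influences
every net-produced species positively and every net-consumed species
negatively. Net stoichiometry (not side membership) decides
produced/consumed, so a catalyst written on both sides contributes no
negative edge. Self-edges are excluded; opposite influences between the
same ordered pair merge into one edge carrying both signs.

"All possible paths" is made finite as *simple* directed paths (no repeated
nodes) up to a configurable cutoff (default: node count, i.e. unbounded for
simple paths). Weighted proximity sums 1/length over these paths; the
signed variant weights each path by the product of per-edge sign sums, so
an edge carrying both signs annihilates every path through it. This keeps
|signed| ≤ unsigned, and both reduce to the obvious hand-countable values
on small graphs. Unreachable species are reported explicitly (never as
distance 0) and excluded from regressions by default, since no principled
finite score exists; a flag includes them with score 0.

Heuristics are scored against a measured D table by ordinary least squares
with intercept; R² then equals the squared Pearson correlation and is
independent of the regression direction, so the choice to regress D on the
score is inconsequential.

## The model library and what it does (not) emulate

The library's oscillator is a mass-action activator–substrate
(Brusselator-type) circuit: constitutive inflow of X, conversion X→Y with
rate b (the feedback-strength parameter), trimolecular recovery 2X+Y→3X,
and linear decay. It has a genuine limit cycle for b > 1 + a² and is the
simplest mass-action mechanism with a robust, tunable period: the obvious
alternative, a delayed-negative-feedback chain, cannot sustain a limit
cycle with mass-action steps alone (it needs steep, Hill-type repression),
and damped oscillations would make spectral peaks and period targets
unreliable. The builder measures
the dimensionless period by ODE integration at build time and rescales all
rate constants to hit `target_period`, so builds are deterministic and the
deterministic period lands within a few percent of target (tests enforce
20%). `count_scale` sets molecule numbers (X swings over roughly 0.5–2.5 ×
count_scale) and hence intrinsic noise.

The standard fixture emulates, at desk scale, a system of two signalling
oscillators with well-separated characteristic frequencies perturbing one
downstream pathway: a slow oscillator (period 500 min, mode ≈ 0.002
cycles/min) coupling into species C1 of a six-species production cascade,
and a fast oscillator (period 100 min, ≈ 0.01 cycles/min) coupling into C2.
Couplings are catalytic mass-action productions whose rate constants the
strength multiplier (0/1/2/10) scales; the coupling fluxes at strength 1
are comparable to the cascade's basal fluxes. Cascade degradation rates are
deliberately heterogeneous (0.05, 0.01, 0.05, 0.005, 0.02, 0.05 per min)
so stage corner frequencies straddle both oscillator frequencies: the slow
oscillation propagates down the chain while the fast one is filtered out
within a stage or two, leaving its influence dominated by low-frequency
envelope components. This is what makes the fixture reproduce the
qualitative phenomenology of interest — the maximally perturbed species
need not be the directly driven one, joint perturbations do not sum, and
which topology heuristic "works" depends on the perturbation source.

What the fixture does *not* emulate: real parameterisations of named
pathways (all species are explicitly analogues), non-mass-action coupling
kinetics, transcriptional delay, extrinsic noise, or cell division. Passing
tests therefore demonstrate properties of the *method* — resolution,
exactness, reproducibility, and the existence of the qualitative effects —
not quantitative predictions about any biological system.

## Numerical conventions and degenerate inputs

* Phases use the four-quadrant angle in (−π, π]; bins with amplitude below
  1e-9·N·max|x| are flagged undefined rather than reported as noise.
* K-S comparison rejects all-zero spectra (no distribution exists) and
  mismatched grids.
* Ties in channel selection are impossible up to floating-point measure
  zero; the strict-inequality cumulative search is the documented
  tie-break.
* `validate_network` returns diagnostics (never raises) and is idempotent;
  simulation refuses invalid or concentration-mode networks.
* Problem sizes in the test suite: ensembles of K = 100 runs of the full
  ten-species fixture over 4000 simulated minutes (~2·10⁵ events per run)
  for the crosstalk analyses; 10⁴ short runs for the master-equation
  exactness check; count_scale 2·10⁴ for the quasi-deterministic/ODE
  agreement check. These sizes were chosen so every ensemble-statistical
  claim is tested at the same (N, δt, K) conditions the method's stated
  0.05 resolution refers to.

## Known limitations

* Custom kinetic laws evaluate through a restricted Python expression
  namespace; they are flexible but slow compared to the compiled
  mass-action path, and α-rescaled custom laws become callables that the
  text dialect cannot serialise.
* The quasi-deterministic model freezes at exact flux-balance states and,
  like the construction it implements, preserves only the *expected* drift,
  not higher moments.
* SBML support covers species, reactions, modifiers and kinetic laws with
  local parameters (Level 3); compartment volumes, units, events and rules
  are ignored or rejected.
* R² against topology scores is a deliberately crude benchmark — it is the
  quantity the heuristics themselves are being judged by, not a recommended
  measure of model fit.
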