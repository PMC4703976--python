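# Methods

## Simulation model

The engine is strictly clock-driven with a fixed global step `DT` (ms).
Every update rule is a user-supplied (or built-in) code snippet containing
the *entire* per-step update — the solver is part of the snippet, so a
forward-Euler model writes the Euler step explicitly and a model wanting
inner sub-steps writes a loop (the Hodgkin–Huxley built-in takes five
DT/5 sub-steps per global step).  Snippets use a restricted C-like grammar:
assignments and compound assignments, arithmetic, comparisons, `&&`/`||`/`!`,
the ternary conditional, counted `for` loops, and a function whitelist
(`exp log sin cos tanh pow sqrt fmax fmin floor abs`, plus `uniform()` /
`normal()` bound to the engine RNG).  `tanh` is included because the graded
synapse of the insect-olfaction model is tanh-shaped.

Token substitution resolves `$(name)` against a symbol table per
(population, snippet kind); the synthesized vectorized routine is compiled
once at simulation setup.  Conditionals become elementwise masks
(`numpy.where`), so each statement inside a branch takes effect exactly
where the condition holds, and *both* ternary branches are evaluated before
selection (routines run under suppressed floating-point warnings; a
non-finite value reaching any state variable aborts the run with
population/variable/step coordinates, unless downgraded to a warning).
Generated sources are plain readable Python and can be dumped next to the
outputs for inspection (`Simulation(..., debug_dump=dir)`).

### Step order and latency convention

One step executes: (1) continuous synapse dynamics; (2) per population, in
registration order: sum `Isyn` through each incoming projection's
apply-input code, then run that projection's decay, advance the neuron
state, evaluate the threshold (level-triggered, every step), push spiker
ids into the population's delay queue, update the last-spike times, apply
the reset, and evaluate outgoing event thresholds; (3) per projection,
deliver the spikes/events read at the projection's delay, accumulating into
`inSyn`; (4) per projection with learning code, apply it over the incoming
synapses of this step's post-synaptic spikers (zero-latency within the
step); (5) rotate all queues and advance the clock.  A spike emitted at
step *k* through a projection with `delay_steps = d` therefore first
affects the target's input at step *k* + 1 + *d*: `DT` is the causal
quantum.  Post-synaptic decay runs immediately *after* apply-input within
the same neuron phase; this ordering is a package convention.

### Determinism

Each population and projection owns an RNG stream spawned from the model
seed in registration order; draws inside snippets consume one full-width
vector per call site in statement order (neuron-id order).  `addtoinSyn`
contributions of one routine invocation are summed per target in a fixed
serial order — ascending pre-synaptic id, then ascending synapse index
(sparse rows keep post indices strictly increasing precisely to pin this
order) — into a scratch buffer of the model's precision, then added to
`inSyn`.  Runs are therefore bit-reproducible for fixed (model, seed,
precision), and dense and sparse storage of the same wiring produce
identical spike trains, which the test suite asserts exactly.  This
deliberately replaces atomic, schedule-dependent GPU-style accumulation
with a deterministic serial order.

### Precision

State arrays, synaptic accumulators and snippet arithmetic run in the
model's precision (`single` or `double`; integer variables stay 64-bit).
Scalar subexpressions involving only parameters are folded in double
precision at generation time.  All reference/oracle comparisons in the test
suite are made in double precision, where the vectorized engine is bitwise
equal to an element-by-element scalar interpreter.

## Built-in models and parameter provenance

* **Izhikevich** — `v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`;
  v integrated as two DT/2 half-steps, u as one DT step; spike at
  v ≥ 30 mV, reset `v = c`, `u += d`.  `c`, `d` (and in the fully variable
  template `a`, `b`) are per-neuron *variables* so heterogeneous populations
  keep the parameter/variable dichotomy (parameters never vary within a
  population).
* **Traub–Miles HH** — gNa = 7.15 µS, ENa = 50 mV, gK = 1.43 µS,
  EK = −95 mV, gl = 0.02672 µS, El = −63.563 mV, C = 0.143 nF (canonical
  values of the cited single-compartment reduction); five Euler sub-steps
  of DT/5.  The α/β rate terms of the x/(eˣ−1) type switch to the analytic
  limit 1 − x/2 for |x| < 10⁻⁶ (l'Hôpital guard; the series error at the
  seam is ~10⁻¹³ relative, well inside double rounding and outside float
  rounding).  Spikes are rising 0 mV crossings detected with a
  previous-voltage variable; there is no engine-level refractory mechanism.
* **Poisson source** — per step draw u ~ U(0,1); spike when
  `u < rate·DT/1000` and the last spike is at least `trefract` ms old.
  The rate is a per-neuron variable so input patterns can be switched
  during a protocol.
* **Synapses** — pulse (`addtoinSyn = g` on pre spike); graded
  (`g·tanh((V_pre − Epre)/Vslope)·DT` per step while `V_pre > Epre`); STDP
  with a piecewise-linear pair kernel: potentiation `aplus·(1 − Δt/tplus)`
  for 0 ≤ Δt ≤ tplus (Δt = t_post − t_pre), depression
  `−aminus·(1 + Δt/tminus)` for −tminus ≤ Δt < 0, zero outside, weights
  hard-clamped to [gmin, gmax] after every update.  The template has one
  additional amplitude `adep`: on each post-synaptic spike, synapses whose
  pre-synaptic neuron did *not* fire within `tplus` are depressed by
  `adep`.  This non-Hebbian term is the mechanism of the primitive
  olfactory learning rule this model family uses — a purely causal pair
  kernel only strengthens the feed-forward pathway and cannot produce the
  activity sparsening the learning benchmark demonstrates.  `adep = 0`
  recovers the pure pair rule.

## Benchmark networks

**Pulse-coupled Izhikevich network** (n neurons, default 1000):
⌊0.8n⌋ excitatory (a = 0.02, b = 0.2, c = −65 + 15r², d = 8 − 6r²,
r ~ U(0,1)) and the rest inhibitory (a = 0.02 + 0.08r, b = 0.25 − 0.05r,
c = −65, d = 2), the canonical randomized heterogeneity of the cited
pulse-coupled model.  Each neuron makes 1000 outgoing connections to
targets drawn uniformly without replacement across the whole network
(capped at n with a logged deviation when n < 1000; self-connections
allowed, as in the all-to-all original).  Excitatory weights 0.5·U(0,1),
inhibitory −U(0,1), delivered as instantaneous current pulses on the next
step (delay 0, DT = 1 ms, two 0.5 ms half-steps for v).  Thalamic drive is
a fresh per-neuron normal draw each step with SD σ; the canonical levels
(5 exc / 2 inh) are identified with the *balanced* regime, so the quiet
baseline is half that, and quiet : balanced : irregular = 1 : 2 : 3 by
construction.  Under these conditions the network fires at ≈ 7–8 Hz per
neuron in the balanced regime with quiet ≪ balanced < irregular, which the
acceptance checks measure over 5 s runs.

**Insect olfaction model**: 100 Poisson projection neurons (PN), 20 lateral
horn interneurons (LHI), N Kenyon cells (KC, configurable; tests use
100–250, the generator defaults to 1000) and 100 decision neurons (DN),
all HH except the PNs.  Wiring: PN→KC pulse synapses (each KC samples 20
of the 100 PNs, weights jittered ±50 %), PN→LHI dense pulse, LHI→KC and
DN→DN graded inhibitory (reversal −92 mV), KC→DN all-to-all STDP synapses
(reversal 0 mV).  The dense/sparse storage choice applies to PN→KC and
KC→DN.  DT = 0.2 ms with five HH sub-steps.  Odors are random 20-PN
subsets presented cyclically: 100 ms at 80 Hz (background 5 Hz) followed
by 200 ms of background.

Published descriptions of this model family do not pin every constant, so
the Poisson rates, conductances and STDP amplitudes are package defaults
chosen once to realise the intended operating regime —
sparse KC activity (KC mean rate well below a tenth of the PN rate) and DN
activity that sparsens after ~20 simulated seconds of learning and does
not when the weights are frozen.  Every constant is recorded with its
source ("benchmark description", "canonical model definition", or
"package default") in the generator's provenance log, emitted next to the
simulation outputs.  One numerical constraint shaped the choices: with
forward Euler at 0.04 ms, strongly synchronized conductance volleys make
the Na-gating update unstable, so the per-synapse conductances are kept
small enough that worst-case simultaneous input stays in the stable range.

### What the generators do and do not emulate

The synthetic drive reproduces the statistical structure the benchmarks
describe (regime scaling, odor episodes, randomized heterogeneity), not
recorded data: there are no neuromodulation, adaptation currents,
conduction-delay distributions or trial-to-trial nonstationarities.
Passing tests therefore demonstrate the correctness of the simulation
machinery and the qualitative network phenomena (rate regimes, sparse
coding, learning direction) at scaled-down sizes — not quantitative
agreement with biological recordings, and not the original hardware
performance figures, which are out of scope.

## Test strategy and problem sizes

Every generated routine is checked against independent scalar references:
closed forms where they exist (Euler recursions, geometric decay), scalar
single-neuron steppers for the Izhikevich and HH templates, and a
tree-walking scalar interpreter plus hand-written per-synapse event loop
that re-simulates whole random small models (≤ 20 neurons, ≤ 50 steps)
element by element — the vectorized engine must match it bitwise in double
precision.  Network-level checks run at scaled sizes chosen for single-core
tractability: 5 s runs of the 1000-neuron Izhikevich network (three seeds),
1.5 s regime-ordering runs at 500 neurons, and two 50 s olfaction runs at
250 KCs for the learning demonstration, comparing DN spike counts in the
matched windows [0, 19.8 s) and [30 s, 49.8 s) — each exactly 33 whole
600 ms odor cycles, so both windows sample identical stimulus phases.

## Known limitations

* Forward-Euler snippets are only as stable as their step size; the engine
  detects non-finite state but does not adapt steps.
* Heterogeneous per-synapse delays are not supported (delays are per
  projection), matching the framework being modelled.
* Graded (event-driven) transmission is evaluated once per global step, so
  sub-step voltage excursions do not transmit.
* `%` follows Python remainder semantics (sign of the divisor), not C.
* Single-precision runs are deterministic but are not expected to match
  double-precision trajectories; oracle equivalence is asserted in double.
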