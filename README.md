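# spikegen

A deterministic, vectorized CPU simulator for spiking neural networks that
are defined *declaratively*: neuron and synapse models are parameter lists
plus short C-like code snippets, and the simulator synthesizes the actual
update routines from those snippets by `$()` token substitution.  It is
aimed at computational neuroscientists who want full control over model
equations (the snippet *is* the solver) without writing simulation loops,
and at anyone studying the behaviour of snippet-defined network models with
bit-reproducible results.

## The model of computation

A network (`NNModel`) is a list of neuron populations and synapse
populations with a global fixed time step `DT`.  A neuron model supplies
three snippets — per-step state update, a threshold condition evaluated
every step (non-zero ⇒ spike), and a reset applied to the spikers.  A
synapse model supplies up to five snippets: code on pre-synaptic spikes, on
pre-synaptic *events* (a condition on pre-synaptic state, e.g. graded
transmission while `V_pre` is depolarised), on post-synaptic spikes
(learning), continuous per-step synapse dynamics, and the event condition
itself.  A post-synaptic model turns the accumulated activation `inSyn`
into the target's input current `Isyn` and decays it, e.g.

```
Isyn += inSyn;          inSyn *= exp(-DT/tau);
```

Within snippets, `$(name)` refers to a variable, parameter, derived
parameter (precomputed once, e.g. `expDecay = exp(-DT/tau)`) or a
predefined symbol (`Isyn`, `inSyn`, `DT`, `t`, `id`, `sT_pre`, `sT_post`).
One simulation step runs: continuous synapse dynamics → neuron phase
(input summation, decay, state update, spike detection, reset, event
detection) → spike/event transmission → post-spike learning → queue
rotation.  Connectivity is dense (all-to-all, optionally masked) or sparse
in YALE/CSR form (row-start + post-index arrays); per-population axonal
delays use circular queues, and a spike emitted at step *k* through a
projection with delay *d* affects its target's input at step *k* + 1 + *d*.
All accumulation runs in a fixed serial order (ascending pre-synaptic id,
then synapse index), so a run is bit-reproducible for a fixed
(model, seed, precision) — there is no scheduling nondeterminism.

Built-in templates: Izhikevich (`v' = 0.04v² + 5v + 140 − u + I`,
`u' = a(bv − u)`, spike at v ≥ 30 mV, reset v = c, u += d), Traub–Miles
Hodgkin–Huxley (5 inner Euler sub-steps per global step; rate functions
guard the removable singularities of x/(eˣ−1) with their analytic limits),
Poisson sources, pulse/graded/STDP synapses, and exponential-decay
post-synaptic integrators.

## Worked example

```python
import spikegen as sg
from spikegen import builtin_models as bm

model = sg.NNModel("demo", dt=1.0)
model.add_neuron_population("P", 1, bm.leaky_integrator(), [0.2, 1.0], [-10.0])
sim = sg.Simulation(model)
sim.step()
print(sim.get_var("P", "V"))
```

prints `[-8.]`: the leaky-integrator snippet
`$(V) += (-$(g)/$(C)*$(V) + $(Isyn))*DT;` advanced V = −10 by one forward
Euler step with g/C = 0.2 and no input.  Driving V above the
`$(V) >= 0.0` threshold makes the neuron spike and the reset snippet
leaves V at −60.

The two benchmark networks are available from the command line:

```bash
spikegen benchmark1 --n 1000 --regime balanced --duration 5000 --seed 1
```

writes spike rasters (two-column text: time in ms, global neuron id), a
summary report and a parameter provenance log, and prints

```
rate[Exc] = 7.303 Hz
rate[Inh] = 6.843 Hz
mean rate = 7.211 Hz
total spikes = 36056
delivered spikes = 36056000
```

— a pulse-coupled network of 800 excitatory and 200 inhibitory Izhikevich
neurons under the balanced (2×) thalamic drive firing at ≈ 8 Hz per neuron,
each spike delivered through 1000 outgoing synapses.  `spikegen benchmark2`
runs the insect-olfaction model (100 Poisson projection neurons, 20 lateral
horn interneurons, N Kenyon cells, 100 decision neurons with STDP);
`spikegen run config.yaml` drives either network from a declarative
configuration file, and `spikegen validate config.yaml` checks a model
definition and reports diagnostics.

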