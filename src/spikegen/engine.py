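"""The fixed-step simulation engine.

The engine works strictly time-step driven with the model's global step
``DT``.  One step executes, in this order:

1. continuous synapse dynamics for every synapse population;
2. the neuron phase, population by population in registration order: sum the
   synaptic input ``Isyn`` through each incoming projection's apply-input
   code, run each projection's post-synaptic decay, advance the neuron state
   by ``sim_code``, evaluate the threshold condition, push the spiking ids
   into the population's delay queue, apply the reset code to the spikers,
   and evaluate outgoing event thresholds;
3. the synapse phase: for every projection, read the pre-synaptic spike (and
   event) ids at the projection's delay and apply the weight-update code per
   existing synapse, accumulating into the target's ``inSyn``;
4. the learning phase: for projections with post-spike learning code, apply
   it over the incoming synapses of this step's post-synaptic spikers;
5. advance all delay queues and the clock.

A spike emitted at step ``k`` through a projection with ``delay_steps = d``
therefore first affects the target's ``Isyn`` at step ``k + 1 + d``: ``DT``
is the causal quantum.  All phases iterate in registration order and all
accumulations run in a fixed serial order, so a run is bit-reproducible for
a fixed (model, seed, precision) — by construction, with no scheduling
nondeterminism.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import codegen
from .connectivity import SpikeQueue
from .model import NNModel, validate_model

__all__ = [
    "SpikeRecord",
    "RunResult",
    "Simulation",
    "SimulationError",
    "run",
    "step",
    "count_delivered_spikes",
]


class SimulationError(RuntimeError):
    """Raised when the simulation state becomes invalid (e.g. non-finite)."""


class SpikeRecord:
    """Append-only, time-ordered record of (time, neuron id) spike pairs."""

    def __init__(self, population: str, id_offset: int = 0):
        self.population = population
        self.id_offset = id_offset
        self._times: list[np.ndarray] = []
        self._ids: list[np.ndarray] = []

    def append(self, t: float, ids: np.ndarray) -> None:
        if ids.size:
            self._times.append(np.full(ids.size, t))
            self._ids.append(ids.copy())

    @property
    def times(self) -> np.ndarray:
        return np.concatenate(self._times) if self._times else np.empty(0)

    @property
    def ids(self) -> np.ndarray:
        """Local (within-population) neuron ids."""
        return np.concatenate(self._ids) if self._ids else np.empty(0, dtype=np.int64)

    @property
    def global_ids(self) -> np.ndarray:
        return self.ids + self.id_offset

    @property
    def count(self) -> int:
        return sum(a.size for a in self._ids)

    def __len__(self) -> int:
        return self.count

    def pairs(self) -> np.ndarray:
        """(n_spikes, 2) array of (time, global id)."""
        return np.column_stack([self.times, self.global_ids.astype(float)])


@dataclass
class RunResult:
    spikes: dict[str, SpikeRecord]
    traces: dict[tuple[str, str], dict]
    summary: dict


class _PopRT:
    __slots__ = ("pop", "S", "sT", "queue", "rng", "sim", "threshold", "reset",
                 "incoming", "outgoing", "last_spikes")

    def __init__(self, pop, dtype, dt, precision, rng, max_delay_steps):
        self.pop = pop
        self.S = pop.initial_state(dtype)
        self.sT = np.full(pop.n, -1.0e10, dtype=dtype)
        self.queue = SpikeQueue(max_delay_steps + 1)
        self.rng = rng
        self.sim, self.threshold, self.reset = codegen.build_neuron_routines(
            pop, dt, precision)
        self.incoming: list[_ProjRT] = []
        self.outgoing: list[_ProjRT] = []
        self.last_spikes = np.empty(0, dtype=np.int64)


class _ProjRT:
    __slots__ = ("sp", "conn", "syn_vars", "psm_vars", "inSyn", "routines",
                 "apply_input", "decay", "event_queue", "rng", "pre_rt", "post_rt",
                 "_all_synapses")

    def __init__(self, sp, dtype, dt, precision, rng, pre_rt, post_rt):
        self.sp = sp
        self.conn = sp.built_projection()
        self.rng = rng
        self.pre_rt = pre_rt
        self.post_rt = post_rt
        self.routines = codegen.build_synapse_routines(sp, dt, precision)
        self.apply_input, self.decay = codegen.build_postsyn_routines(sp, dt, precision)
        self.event_queue = (
            SpikeQueue(sp.delay_steps + 1) if self.routines["evnt_threshold"] else None
        )
        self._all_synapses = None

        # per-synapse variable storage, flat over the synapse index
        self.syn_vars = {}
        if sp.conductance_mode == "individual":
            n_flat = (
                self.conn.n_conn
                if self.conn.kind == "sparse"
                else self.conn.n_pre * self.conn.n_post
            )
            for nm, vt, init in zip(
                sp.weight_model.var_names, sp.weight_model.var_types,
                sp.weight_init_var_values,
            ):
                vdt = np.int64 if vt == "integer" else dtype
                if nm in sp.syn_var_arrays:
                    arr = np.asarray(sp.syn_var_arrays[nm], dtype=vdt).copy()
                    if arr.size != n_flat:
                        raise SimulationError(
                            f"{sp.name}: per-synapse values for {nm!r} have wrong length")
                elif np.ndim(init) == 0:
                    arr = np.full(n_flat, init, dtype=vdt)
                else:
                    arr = np.asarray(init, dtype=vdt).reshape(-1).copy()
                    if arr.size != n_flat:
                        raise SimulationError(
                            f"{sp.name}: initial array for {nm!r} must have "
                            f"{n_flat} entries, got {arr.size}")
                self.syn_vars[nm] = arr

        self.psm_vars = {}
        for nm, vt, init in zip(
            sp.postsyn_model.var_names, sp.postsyn_model.var_types,
            sp.postsyn_init_var_values,
        ):
            vdt = np.int64 if vt == "integer" else dtype
            self.psm_vars[nm] = (
                np.full(sp.post.n, init, dtype=vdt)
                if np.ndim(init) == 0
                else np.asarray(init, dtype=vdt).copy()
            )
        self.inSyn = np.zeros(sp.post.n, dtype=dtype)

    def all_synapses(self):
        if self._all_synapses is None:
            if self.conn.kind == "sparse":
                self._all_synapses = self.conn.gather_rows(np.arange(self.conn.n_pre))
            else:
                self._all_synapses = self.conn.all_synapses()
        return self._all_synapses

    def invoke(self, kind: str, gather, t: float) -> None:
        syn, pre_of, post_of = gather
        self.routines[kind].entry(
            self.syn_vars, self.pre_rt.S, self.post_rt.S, self.inSyn,
            self.pre_rt.sT, self.post_rt.sT, syn, pre_of, post_of, t, self.rng,
        )


class Simulation:
    """Mutable simulation state for one model.

    Building a ``Simulation`` compiles all update routines, allocates state
    arrays (at the model's precision), seeds one RNG stream per population
    and projection from the model seed, and primes the delay queues.  The
    state can then be advanced with :meth:`step`/:meth:`run`; state arrays
    are accessible (and assignable) between calls for user-driven protocols.
    """

    def __init__(
        self,
        model: NNModel,
        *,
        record_spikes: bool | Sequence[str] = True,
        record_vars: Sequence[tuple[str, str, Sequence[int] | None]] = (),
        abort_on_nonfinite: bool = True,
        validate: bool = True,
        debug_dump: str | None = None,
    ):
        if validate:
            diags = validate_model(model)
            if diags:
                raise SimulationError(
                    "model failed validation:\n" + "\n".join(map(str, diags)))
        self.model = model
        self.dtype = np.float32 if model.precision == "single" else np.float64
        self.abort_on_nonfinite = abort_on_nonfinite
        self.t = 0.0
        self.step_index = 0

        ss = np.random.SeedSequence(model.seed)
        children = ss.spawn(len(model.neuron_populations) + len(model.synapse_populations))
        max_delay: dict[str, int] = {p.name: 0 for p in model.neuron_populations}
        for sp in model.synapse_populations:
            max_delay[sp.pre.name] = max(max_delay[sp.pre.name], sp.delay_steps)

        self.pops: dict[str, _PopRT] = {}
        for i, pop in enumerate(model.neuron_populations):
            self.pops[pop.name] = _PopRT(
                pop, self.dtype, model.dt, model.precision,
                np.random.default_rng(children[i]), max_delay[pop.name])

        self.projs: dict[str, _ProjRT] = {}
        off = len(model.neuron_populations)
        for j, sp in enumerate(model.synapse_populations):
            prt = _ProjRT(sp, self.dtype, model.dt, model.precision,
                          np.random.default_rng(children[off + j]),
                          self.pops[sp.pre.name], self.pops[sp.post.name])
            self.projs[sp.name] = prt
            self.pops[sp.post.name].incoming.append(prt)
            self.pops[sp.pre.name].outgoing.append(prt)

        if record_spikes is True:
            rec_pops = [p.name for p in model.neuron_populations]
        elif record_spikes is False:
            rec_pops = []
        else:
            rec_pops = list(record_spikes)
        self.spike_records = {
            nm: SpikeRecord(nm, model.neuron_population(nm).id_offset) for nm in rec_pops
        }

        #: cumulative wall-clock seconds per step phase (debug aid)
        self.phase_times = {"dynamics": 0.0, "neuron": 0.0, "synapse": 0.0,
                            "learning": 0.0}
        self.traces: dict[tuple[str, str], dict] = {}
        for spec in record_vars:
            pop_name, var, ids = spec
            ids = (np.arange(model.neuron_population(pop_name).n)
                   if ids is None else np.asarray(ids, dtype=np.int64))
            self.traces[(pop_name, var)] = {"ids": ids, "times": [], "values": []}
        self._sample_traces()

        if debug_dump:
            self.dump_generated_source(debug_dump)

    # -- public helpers
    def get_var(self, pop: str, var: str) -> np.ndarray:
        return self.pops[pop].S[var]

    def set_var(self, pop: str, var: str, values) -> None:
        arr = self.pops[pop].S[var]
        arr[...] = values

    def dump_generated_source(self, directory: str) -> None:
        """Write every generated routine's source as plain text (one file per
        population and snippet kind), for human inspection."""
        os.makedirs(directory, exist_ok=True)
        for rt in self.pops.values():
            for r in (rt.sim, rt.threshold, rt.reset):
                if r is not None:
                    self._dump_one(directory, r)
        for pr in self.projs.values():
            for r in list(pr.routines.values()) + [pr.apply_input, pr.decay]:
                if r is not None:
                    self._dump_one(directory, r)

    @staticmethod
    def _dump_one(directory: str, routine) -> None:
        owner, kind = routine.provenance
        path = os.path.join(directory, f"{owner}_{kind}.py")
        with open(path, "w") as fh:
            fh.write(routine.source_text)

    # -- stepping
    def step(self) -> None:
        """Advance the whole network by one global time step."""
        model = self.model
        t = self.t
        tick = time.perf_counter()

        # (1) continuous synapse dynamics
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            if pr.routines["dynamics"] is not None:
                pr.invoke("dynamics", pr.all_synapses(), t)
        tick = self._lap("dynamics", tick)

        # (2) neuron phase
        for pop in model.neuron_populations:
            rt = self.pops[pop.name]
            Isyn = np.zeros(pop.n, dtype=self.dtype)
            for pr in rt.incoming:
                pr.apply_input.entry(pr.psm_vars, rt.S, pr.inSyn, Isyn, t, pr.rng)
                if pr.decay is not None:
                    pr.decay.entry(pr.psm_vars, rt.S, pr.inSyn, t, pr.rng)
            if rt.sim is not None:
                rt.sim.entry(rt.S, Isyn, rt.sT, t, rt.rng)
            ids = np.empty(0, dtype=np.int64)
            if rt.threshold is not None:
                mask = rt.threshold.entry(rt.S, Isyn, rt.sT, t, rt.rng)
                ids = np.flatnonzero(mask)
                if ids.size:
                    rt.sT[ids] = t
                    if rt.reset is not None:
                        rt.reset.entry(rt.S, Isyn, rt.sT, ids, t, rt.rng)
            rt.queue.write(ids)
            rt.last_spikes = ids
            for pr in rt.outgoing:
                if pr.event_queue is not None:
                    emask = pr.routines["evnt_threshold"].entry(rt.S, Isyn, rt.sT, t, rt.rng)
                    pr.event_queue.write(np.flatnonzero(emask))
            rec = self.spike_records.get(pop.name)
            if rec is not None:
                rec.append(t, ids)
            if self.abort_on_nonfinite:
                self._check_finite(pop.name, rt)
        tick = self._lap("neuron", tick)

        # (3) synapse phase: spike and event transmission
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            d = sp.delay_steps
            if pr.routines["sim"] is not None:
                ids = pr.pre_rt.queue.read(d)
                if ids.size:
                    pr.invoke("sim", pr.conn.gather_rows(ids), t)
            if pr.routines["evnt"] is not None:
                eids = pr.event_queue.read(d)
                if eids.size:
                    pr.invoke("evnt", pr.conn.gather_rows(eids), t)
        tick = self._lap("synapse", tick)

        # (4) post-synaptically triggered learning
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            if pr.routines["learn"] is not None:
                pids = pr.post_rt.queue.read(0)
                if pids.size:
                    pr.invoke("learn", pr.conn.gather_cols(pids), t)
        self._lap("learning", tick)

        # (5) rotate queues, advance the clock
        for rt in self.pops.values():
            rt.queue.advance()
        for pr in self.projs.values():
            if pr.event_queue is not None:
                pr.event_queue.advance()
        self.step_index += 1
        self.t = self.step_index * model.dt
        self._sample_traces()

    def run(self, duration: float) -> None:
        """Advance by ``round(duration / dt)`` steps (duration in ms)."""
        if duration < 0:
            raise ValueError("duration must be non-negative")
        steps = int(round(duration / self.model.dt))
        if abs(steps * self.model.dt - duration) > 1e-6 * max(1.0, abs(duration)):
            raise ValueError(
                f"duration {duration} ms is not a whole number of {self.model.dt} ms steps")
        for _ in range(steps):
            self.step()

    # -- internals
    def _lap(self, phase: str, tick: float) -> float:
        now = time.perf_counter()
        self.phase_times[phase] += now - tick
        return now

    def _sample_traces(self) -> None:
        for (pop_name, var), tr in self.traces.items():
            tr["times"].append(self.t)
            tr["values"].append(self.pops[pop_name].S[var][tr["ids"]].copy())

    def _check_finite(self, name: str, rt: _PopRT) -> None:
        for var, arr in rt.S.items():
            if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise SimulationError(
                    f"non-finite value in population {name!r}, variable {var!r}, "
                    f"neuron {bad}, at step {self.step_index}")

    def finalize_traces(self) -> dict:
        out = {}
        for key, tr in self.traces.items():
            out[key] = {
                "ids": tr["ids"],
                "times": np.asarray(tr["times"]),
                "values": np.asarray(tr["values"]),
            }
        return out

    def result(self) -> RunResult:
        total = sum(r.count for r in self.spike_records.values())
        summary = {
            "steps": self.step_index,
            "t_ms": self.t,
            "total_spikes": total,
        }
        return RunResult(dict(self.spike_records), self.finalize_traces(), summary)


def step(sim: Simulation) -> Simulation:
    """Advance a simulation by one global step (functional-style wrapper)."""
    sim.step()
    return sim


def run(
    model: NNModel,
    duration: float,
    record_spikes: bool | Sequence[str] = True,
    record_vars: Sequence[tuple[str, str, Sequence[int] | None]] = (),
    **kwargs,
) -> RunResult:
    """Simulate ``model`` for ``duration`` ms and return the recordings.

    Deterministic for a fixed (model, seed, precision): repeated calls yield
    identical spike rasters and traces.
    """
    sim = Simulation(model, record_spikes=record_spikes, record_vars=record_vars, **kwargs)
    sim.run(duration)
    return sim.result()


def count_delivered_spikes(model: NNModel, spike_records: Mapping[str, SpikeRecord]) -> int:
    """Total synaptic deliveries: each spike counts once per outgoing synapse.

    This is the throughput-relevant quantity — a spike from a neuron with
    1000 outgoing connections is delivered 1000 times.
    """
    total = 0
    for pop in model.neuron_populations:
        rec = spike_records.get(pop.name)
        if rec is None or rec.count == 0:
            continue
        per_neuron = np.bincount(rec.ids, minlength=pop.n)
        for sp in model.outgoing(pop.name):
            out_deg = sp.built_projection().out_degree()
            total += int(per_neuron @ out_deg)
    return total
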