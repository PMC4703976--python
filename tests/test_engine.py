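"""Engine semantics: step order, latency, determinism, oracle equivalence."""

import numpy as np
import pytest

from spikegen import builtin_models as bm
from spikegen.engine import Simulation, SimulationError, count_delivered_spikes, run
from spikegen.model import NNModel, NeuronModel, WeightUpdateModel

from _scalar_oracle import ScalarSimulation


def _driver(rate=0.34):
    """Deterministic pacemaker: spikes whenever the ramp crosses 1."""
    return NeuronModel(
        "driver", ("x",), ("double",), param_names=("rate",),
        sim_code="$(x) += $(rate)*DT;",
        threshold_condition_code="$(x) >= 1.0",
        reset_code="$(x) -= 1.0;",
    )


def _spike_at(step):
    """Unit that spikes exactly once, at the given step index."""
    return NeuronModel(
        "once", ("x",), ("double",), param_names=("k",),
        sim_code="$(x) += 1.0;",
        threshold_condition_code="$(x) == $(k) + 1.0",
        reset_code="",
    )


class TestStepSemantics:
    def test_leaky_integrator_closed_form(self):
        # V_k = V_0 * (1 - g*DT/C)^k with zero input
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("P", 1, bm.leaky_integrator(), [0.2, 1.0], [-10.0])
        sim = Simulation(m)
        for k in range(1, 21):
            sim.step()
            assert sim.get_var("P", "V")[0] == pytest.approx(-10.0 * 0.8 ** k)

    def test_zero_duration_run_leaves_state_unchanged(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("P", 2, bm.leaky_integrator(), [0.2, 1.0], [-10.0])
        res = run(m, 0.0)
        assert res.summary["steps"] == 0
        assert res.summary["t_ms"] == 0.0
        assert res.spikes["P"].count == 0

    @pytest.mark.parametrize("delay", [0, 1, 3])
    def test_transmission_latency_is_emission_plus_one_plus_delay(self, delay):
        spike_step = 2
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 1, _spike_at(spike_step), [float(spike_step)], [0.0])
        m.add_neuron_population("B", 1, bm.leaky_integrator(), [0.0, 1.0], [-50.0])
        m.add_synapse_population("AB", "A", "B", bm.pulse_synapse(),
                                 "dense", "individual", delay, bm.delta_current(),
                                 weight_init_vars=[1.0])
        sim = Simulation(m)
        changed_at = None
        for k in range(12):
            sim.step()
            if changed_at is None and sim.get_var("B", "V")[0] != -50.0:
                changed_at = k  # step index of the step that consumed the pulse
        assert sim.spike_records["A"].times.tolist() == [float(spike_step)]
        assert changed_at == spike_step + 1 + delay

    def test_record_spec_restricts_recording(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 1, _driver(), [0.4], [0.0])
        m.add_neuron_population("B", 1, _driver(), [0.4], [0.0])
        res = run(m, 20.0, record_spikes=["B"])
        assert set(res.spikes) == {"B"}
        assert res.spikes["B"].count > 0

    def test_zero_input_silence(self):
        """Subthreshold initial conditions, no drive => no spikes, ever."""
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 5, bm.leaky_integrator(), [0.2, 1.0], [-50.0])
        m.add_neuron_population("B", 5, bm.izhikevich(), [0.02, 0.2],
                                [-65.0, -13.0, -65.0, 8.0])
        m.add_synapse_population("AB", "A", "B", bm.pulse_synapse(),
                                 "dense", "individual", 0, bm.delta_current(),
                                 weight_init_vars=[0.5])
        res = run(m, 500.0)
        assert all(rec.count == 0 for rec in res.spikes.values())

    def test_nonfinite_state_aborts_with_coordinates(self):
        blower = NeuronModel("blow", ("V",), ("double",),
                             sim_code="$(V) = exp($(V)); $(V) = $(V)*$(V);")
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("P", 2, blower, [], [40.0])
        sim = Simulation(m)
        with pytest.raises(SimulationError, match="population 'P'.*variable 'V'"):
            for _ in range(50):
                sim.step()
        # downgraded check lets the run continue
        sim2 = Simulation(m, abort_on_nonfinite=False)
        for _ in range(5):
            sim2.step()


class TestDeterminism:
    def _net(self, seed=11, precision="double"):
        m = NNModel("t", dt=1.0, seed=seed, precision=precision)
        m.add_neuron_population("E", 12, bm.izhikevich_thalamic(),
                                [0.02, 0.2, 5.0], [-65.0, -13.0, -65.0, 8.0])
        sp = m.add_synapse_population("EE", "E", "E", bm.pulse_synapse(),
                                      "sparse", "individual", 1,
                                      bm.exp_decay_current(),
                                      weight_init_vars=[0.0], postsyn_params=[2.0])
        rng = np.random.default_rng(99)
        pairs = [(i, j) for i in range(12) for j in range(12)
                 if i != j and rng.random() < 0.4]
        sp.connect(pairs, {"g": 0.5 * rng.random(len(pairs))})
        return m

    def test_bit_reproducible_across_repeated_runs(self):
        results = []
        for _ in range(2):
            res = run(self._net(), 300.0)
            results.append(res)
        a, b = results
        assert np.array_equal(a.spikes["E"].times, b.spikes["E"].times)
        assert np.array_equal(a.spikes["E"].ids, b.spikes["E"].ids)

    def test_different_seeds_differ(self):
        a = run(self._net(seed=1), 200.0)
        b = run(self._net(seed=2), 200.0)
        assert (a.spikes["E"].count != b.spikes["E"].count
                or not np.array_equal(a.spikes["E"].times, b.spikes["E"].times))


class TestCountDeliveredSpikes:
    def test_out_degree_weighting(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 2, _driver(), [0.0], [0.0])
        m.add_neuron_population("B", 8, bm.leaky_integrator(), [0.2, 1.0], [-50.0])
        sp = m.add_synapse_population("AB", "A", "B", bm.pulse_synapse(),
                                      "sparse", "individual", 0, bm.delta_current(),
                                      weight_init_vars=[0.0])
        # out-degrees: neuron 0 -> 3 targets, neuron 1 -> 5 targets
        pairs = [(0, j) for j in range(3)] + [(1, j) for j in range(5)]
        sp.connect(pairs, {"g": np.full(len(pairs), 0.1)})
        sim = Simulation(m)
        rec = sim.spike_records["A"]
        rec.append(0.0, np.array([0]))
        rec.append(1.0, np.array([1]))
        rec.append(2.0, np.array([0, 1]))
        assert count_delivered_spikes(m, sim.spike_records) == 3 + 5 + 8

    def test_no_spikes_gives_zero(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 2, _driver(), [0.0], [0.0])
        sim = Simulation(m)
        assert count_delivered_spikes(m, sim.spike_records) == 0


# ---------------------------------------------------------------- oracle equivalence


def _random_pulse_net(seed, connectivity="sparse", delay=1):
    """<=20 neurons: noisy Izhikevich drivers onto leaky integrators."""
    rng = np.random.default_rng(seed)
    m = NNModel("t", dt=1.0, seed=seed)
    m.add_neuron_population("E", 8, bm.izhikevich_thalamic(),
                            [0.02, 0.2, 6.0], [-65.0, -13.0, -65.0, 8.0])
    m.add_neuron_population("L", 6, bm.leaky_integrator(), [0.1, 1.0], [-30.0])
    sp = m.add_synapse_population("EL", "E", "L", bm.pulse_synapse(),
                                  connectivity, "individual", delay,
                                  bm.exp_decay_current(),
                                  weight_init_vars=[0.0], postsyn_params=[3.0])
    pairs = [(i, j) for i in range(8) for j in range(6) if rng.random() < 0.5]
    w = 4.0 * rng.random(len(pairs))
    if connectivity == "sparse":
        sp.connect(pairs, {"g": w})
    else:
        mask = np.zeros((8, 6), dtype=bool)
        g = np.zeros((8, 6))
        for (i, j), v in zip(pairs, w):
            mask[i, j] = True
            g[i, j] = v
        sp.set_dense_mask(mask)
        sp.weight_init_var_values = [g]
    return m


def _graded_stdp_net(seed):
    """Drivers with graded and plastic synapses, exercising events,
    learning and synapse-variable updates."""
    m = NNModel("t", dt=0.5, seed=seed)
    m.add_neuron_population("A", 4, _driver(), [0.21], [0.0])
    m.add_neuron_population("B", 3, _driver(), [0.13], [0.05])
    sp = m.add_synapse_population(
        "AB", "A", "B", bm.stdp_synapse(), "sparse", "individual", 2,
        bm.exp_decay_current(),
        weight_params=[0.05, 0.08, 0.001, 4.0, 6.0, 0.0, 0.4],
        weight_init_vars=[0.0], postsyn_params=[2.0])
    pairs = [(i, j) for i in range(4) for j in range(3) if (i + j) % 2 == 0]
    sp.connect(pairs, {"g": np.linspace(0.1, 0.3, len(pairs))})
    graded_x = WeightUpdateModel(
        "gradedX", ("g",), ("double",), param_names=("thr",),
        evnt_threshold="$(x_pre) > $(thr)",
        sim_code_evnt="addtoinSyn = $(g) * ($(x_pre) - $(thr)) * DT;")
    m.add_synapse_population(
        "BA", "B", "A", graded_x, "dense", "global", 0,
        bm.exp_decay_current(),
        weight_params=[0.5], weight_init_vars=[0.02], postsyn_params=[1.5])
    return m


@pytest.mark.parametrize("factory,seed,steps", [
    (lambda s: _random_pulse_net(s, "sparse", delay=1), 3, 50),
    (lambda s: _random_pulse_net(s, "dense", delay=0), 4, 50),
    (_graded_stdp_net, 5, 50),
])
def test_vectorized_engine_equals_scalar_interpreter(factory, seed, steps):
    """The vectorized engine's double-precision trajectory is bitwise equal
    to the element-by-element scalar interpreter's."""
    sim = Simulation(factory(seed))
    oracle = ScalarSimulation(factory(seed))
    for _ in range(steps):
        sim.step()
        oracle.step()
        for name, rt in oracle.pops.items():
            for var, arr in rt["vars"].items():
                got = sim.get_var(name, var)
                assert np.array_equal(got, arr), (name, var, sim.step_index)
    for name, rec in sim.spike_records.items():
        expect = oracle.pops[name]["spikes"]
        got = list(zip(rec.times.tolist(), rec.ids.tolist()))
        assert got == [(t, i) for t, i in expect], name
    for name, pr in oracle.projs.items():
        for var, arr in pr["syn_vars"].items():
            assert np.array_equal(sim.projs[name].syn_vars[var], arr), (name, var)
        assert np.array_equal(sim.projs[name].inSyn, pr["inSyn"]), name


def test_dense_and_sparse_runs_have_identical_spike_trains():
    """Same wiring stored dense (masked) vs sparse: identical spikes."""
    res = {}
    for kind in ("sparse", "dense"):
        res[kind] = run(_random_pulse_net(7, kind), 200.0)
    for pop in res["sparse"].spikes:
        a, b = res["sparse"].spikes[pop], res["dense"].spikes[pop]
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.ids, b.ids)
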