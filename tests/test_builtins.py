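"""Built-in templates against their scalar reference implementations."""

import numpy as np
import pytest

from spikegen import builtin_models as bm
from spikegen.engine import Simulation, run
from spikegen.model import NNModel

STDP_PARAMS = {"aplus": 0.1, "aminus": 0.15, "tplus": 20.0, "tminus": 40.0,
               "gmin": 0.0, "gmax": 1.0}


class TestIzhikevich:
    def _sim(self, I=0.0, v0=-65.0, u0=-13.0):
        m = NNModel("izh", dt=1.0)
        m.add_neuron_population("P", 1, bm.izhikevich(), [0.02, 0.2],
                                [v0, u0, -65.0, 8.0])
        return Simulation(m)

    def test_subthreshold_drift_no_spike_over_100_steps(self):
        v, u = -65.0, -13.0
        for _ in range(100):
            v, u, spiked = bm.izhikevich_step_reference(v, u, 0.02, 0.2, 0.0)
            assert not spiked
        assert -75.0 < v < -65.0  # drifts toward the ~-70 mV rest point

    def test_engine_matches_scalar_reference_step_for_step(self):
        sim = self._sim()
        v, u = -65.0, -13.0
        for k in range(300):
            sim.step()
            v, u, spiked = bm.izhikevich_step_reference(v, u, 0.02, 0.2, 0.0)
            if spiked:
                v, u = -65.0, u + 8.0
            assert sim.get_var("P", "v")[0] == pytest.approx(v, abs=1e-12)
            assert sim.get_var("P", "u")[0] == pytest.approx(u, abs=1e-12)

    def test_sustained_regular_firing_under_constant_current(self):
        """Constant I=10 with regular-spiking parameters: sustained firing
        with tightly bounded inter-spike intervals after the transient."""
        v, u = -65.0, -13.0
        spikes = []
        for k in range(3000):
            v, u, spiked = bm.izhikevich_step_reference(v, u, 0.02, 0.2, 10.0)
            if spiked:
                spikes.append(k)
                v, u = -65.0, u + 8.0
        assert len(spikes) > 20
        isis = np.diff(spikes)[5:]  # drop the adaptation transient
        med = np.median(isis)
        assert 40.0 < med < 65.0  # ~20 Hz tonic firing
        assert np.all(np.abs(isis - med) <= 0.35 * med)

    def test_reset_semantics(self):
        sim = self._sim()
        sim.set_var("P", "v", 31.0)  # force above the 30 mV cutoff
        u0 = sim.get_var("P", "u")[0]
        sim.step()
        # v was driven over threshold during the step -> reset applied
        assert sim.spike_records["P"].count == 1
        assert sim.get_var("P", "v")[0] == -65.0
        assert sim.get_var("P", "u")[0] > u0  # u increased by d after its drift step


class TestTraubMiles:
    def _hh_model(self, n=1):
        m = NNModel("hh", dt=0.2)
        rest = bm.hh_rest_state()
        tm = bm.traub_miles()
        m.add_neuron_population("H", n, tm,
                                [bm.TRAUB_MILES_PARAMS[k] for k in tm.param_names],
                                [rest["V"], rest["m"], rest["h"], rest["n"], rest["V"]])
        return m

    def test_template_matches_scalar_reference(self):
        sim = Simulation(self._hh_model())
        rest = bm.hh_rest_state()
        V, mg, hg, ng = rest["V"], rest["m"], rest["h"], rest["n"]
        for _ in range(100):
            sim.step()
            V, mg, hg, ng = bm.traub_miles_step_reference(V, mg, hg, ng, 0.0)
            assert sim.get_var("H", "V")[0] == pytest.approx(V, abs=1e-9)
            assert sim.get_var("H", "m")[0] == pytest.approx(mg, abs=1e-12)

    def test_settles_to_rest_without_input(self):
        res = run(self._hh_model(n=3), 500.0)
        assert res.spikes["H"].count == 0

    def test_gating_variables_stay_in_unit_interval(self):
        sim = Simulation(self._hh_model())
        for _ in range(500):
            sim.step()
            for g in ("m", "h", "n"):
                assert 0.0 <= sim.get_var("H", g)[0] <= 1.0


class TestHHRates:
    # removable singularities: alpha_m at -52, beta_m at -25, alpha_n at -50
    LIMITS = [("alpha_m", -52.0, 1.28), ("beta_m", -25.0, 1.4), ("alpha_n", -50.0, 0.16)]

    @pytest.mark.parametrize("name,V,limit", LIMITS)
    def test_exact_singular_point_returns_the_limit(self, name, V, limit):
        r = bm.hh_rates_safe(V)
        assert np.isfinite(r[name])
        assert r[name] == pytest.approx(limit, rel=1e-9)

    @pytest.mark.parametrize("name,V,limit", LIMITS)
    def test_continuity_across_the_guard(self, name, V, limit):
        for eps in (1e-6, -1e-6, 1e-7, -1e-7):
            val = bm.hh_rates_safe(V + eps)[name]
            assert val == pytest.approx(limit, rel=1e-6)

    def test_far_from_singularities_matches_naive_formula(self):
        V = np.array([-80.0, -60.0, -40.0, 0.0, 20.0])
        r = bm.hh_rates_safe(V)
        naive_am = 0.32 * (-52.0 - V) / (np.exp((-52.0 - V) / 4.0) - 1.0)
        naive_bm = 0.28 * (V + 25.0) / (np.exp((V + 25.0) / 5.0) - 1.0)
        naive_an = 0.032 * (-50.0 - V) / (np.exp((-50.0 - V) / 5.0) - 1.0)
        np.testing.assert_allclose(r["alpha_m"], naive_am, rtol=1e-14)
        np.testing.assert_allclose(r["beta_m"], naive_bm, rtol=1e-14)
        np.testing.assert_allclose(r["alpha_n"], naive_an, rtol=1e-14)

    def test_finite_for_extreme_voltages(self):
        r = bm.hh_rates_safe(np.array([-500.0, 500.0]))
        for name in ("alpha_m", "beta_m", "alpha_n"):
            assert np.all(np.isfinite(r[name]))


class TestPoisson:
    def test_long_run_rate_within_three_standard_errors(self):
        """50 sources at 20 Hz for 100 s: count within 3 sqrt(N) of nominal."""
        n, rate, T = 50, 20.0, 100_000.0
        m = NNModel("poi", dt=1.0, seed=42)
        m.add_neuron_population("S", n, bm.poisson(), [0.0], [0.0, rate])
        res = run(m, T)
        expect = n * rate * T / 1000.0
        count = res.spikes["S"].count
        assert abs(count - expect) < 3.0 * np.sqrt(expect)

    def test_refractory_gap_enforced(self):
        m = NNModel("poi", dt=1.0, seed=7)
        m.add_neuron_population("S", 5, bm.poisson(), [5.0], [0.0, 400.0])
        res = run(m, 2000.0)
        rec = res.spikes["S"]
        for i in range(5):
            ts = np.sort(rec.times[rec.ids == i])
            if ts.size > 1:
                assert np.min(np.diff(ts)) >= 5.0


class TestExpDecayPostSyn:
    def test_impulse_response_is_exact_geometric_decay(self):
        """After a single pulse, inSyn follows inSyn0 * expDecay^k exactly."""
        from test_engine import _spike_at
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 1, _spike_at(0), [0.0], [0.0])
        m.add_neuron_population("B", 1, bm.leaky_integrator(), [0.2, 1.0], [-50.0])
        m.add_synapse_population("AB", "A", "B", bm.pulse_synapse(),
                                 "dense", "individual", 0, bm.exp_decay_current(),
                                 weight_init_vars=[1.0], postsyn_params=[5.0])
        sim = Simulation(m)
        sim.step()  # spike emitted and delivered: inSyn = 1
        lam = np.exp(-1.0 / 5.0)
        inSyn = sim.projs["AB"].inSyn
        assert inSyn[0] == 1.0
        expect = 1.0
        for k in range(1, 30):
            sim.step()
            expect = expect * lam  # same multiply sequence: exact in double
            assert inSyn[0] == expect
            assert inSyn[0] == pytest.approx(lam ** k, rel=1e-12)


class TestSTDP:
    def test_peak_potentiation_at_coincidence(self):
        assert bm.stdp_kernel(0.0, STDP_PARAMS) == STDP_PARAMS["aplus"]

    @pytest.mark.parametrize("dt", [-41.0, 20.001, 100.0, -1e6])
    def test_zero_outside_kernel_support(self, dt):
        assert bm.stdp_kernel(dt, STDP_PARAMS) == 0.0

    def test_linear_falloff_and_depression_branch(self):
        assert bm.stdp_kernel(10.0, STDP_PARAMS) == pytest.approx(0.05)
        assert bm.stdp_kernel(-20.0, STDP_PARAMS) == pytest.approx(-0.075)

    def test_clamping_at_bounds(self):
        assert bm.stdp_update(0.0, STDP_PARAMS, g=STDP_PARAMS["gmax"]) == STDP_PARAMS["gmax"]
        assert bm.stdp_update(-1.0, STDP_PARAMS, g=0.0) == 0.0

    def test_weights_remain_clamped_through_simulation(self):
        from test_engine import _driver
        m = NNModel("t", dt=1.0, seed=0)
        m.add_neuron_population("A", 4, _driver(), [0.3], [0.0])
        m.add_neuron_population("B", 4, _driver(), [0.23], [0.1])
        sp = m.add_synapse_population(
            "AB", "A", "B", bm.stdp_synapse(), "dense", "individual", 0,
            bm.exp_decay_current(),
            weight_params=[0.2, 0.3, 0.001, 20.0, 40.0, 0.05, 0.5],
            weight_init_vars=[0.3], postsyn_params=[2.0])
        sim = Simulation(m)
        for _ in range(300):
            sim.step()
            g = sim.projs["AB"].syn_vars["g"]
            assert np.all(g >= 0.05) and np.all(g <= 0.5)
        assert not np.allclose(sim.projs["AB"].syn_vars["g"], 0.3)  # learning happened


class TestGraded:
    def test_no_transmission_while_below_event_threshold(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 2, bm.leaky_integrator(), [0.0, 1.0], [-60.0])
        m.add_neuron_population("B", 1, bm.leaky_integrator(), [0.0, 1.0], [-60.0])
        m.add_synapse_population("AB", "A", "B", bm.graded_synapse(),
                                 "dense", "global", 0, bm.exp_decay_current(),
                                 weight_params=[-30.0, 10.0],
                                 weight_init_vars=[0.5], postsyn_params=[2.0])
        sim = Simulation(m)
        for _ in range(20):
            sim.step()
        assert sim.projs["AB"].inSyn[0] == 0.0
        # raising one pre neuron above threshold starts transmission
        sim.set_var("A", "V", np.array([-60.0, -20.0]))
        sim.step()
        assert sim.projs["AB"].inSyn[0] > 0.0


class TestSnippetExport:
    def test_every_builtin_exports_its_snippets(self, tmp_path):
        for tmpl in (bm.izhikevich(), bm.traub_miles(), bm.poisson(),
                     bm.pulse_synapse(), bm.graded_synapse(), bm.stdp_synapse(),
                     bm.exp_decay_current(), bm.exp_cond(), bm.delta_current()):
            snippets = bm.snippet_set(tmpl)
            assert snippets, tmpl.name
            paths = bm.write_snippets(tmpl, tmp_path / "snips")
            assert len(paths) == len(snippets)
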