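"""Token substitution and routine synthesis."""

import numpy as np
import pytest

from spikegen import builtin_models as bm
from spikegen.codegen import (
    SnippetError,
    SymbolTable,
    build_neuron_routines,
    build_postsyn_routines,
    build_synapse_routines,
    referenced_tokens,
    substitute_tokens,
)
from spikegen.model import NNModel, NeuronModel


WORKED_SNIPPET = "$(V)+=(-$(g)/$(C)*$(V)+$(Isyn))*DT;"
WORKED_TABLE = {"V": "V_arr[id]", "g": "0.2", "C": "1.0", "Isyn": "Isyn_val"}


class TestSubstituteTokens:
    def test_worked_example(self):
        out = substitute_tokens(WORKED_SNIPPET, WORKED_TABLE)
        assert out == "V_arr[id]+=(-0.2/1.0*V_arr[id]+Isyn_val)*DT;"

    def test_text_without_tokens_is_identity(self):
        text = "x += exp(y)*DT; // comment"
        assert substitute_tokens(text, {}) == text

    def test_unresolved_token_names_the_token(self):
        with pytest.raises(SnippetError, match=r"\$\(W\)"):
            substitute_tokens("$(W)", {"V": "v"})

    @pytest.mark.parametrize("text", ["$(V", "$V", "$()", "$(9x)"])
    def test_malformed_tokens_report_offset(self, text):
        with pytest.raises(SnippetError, match="offset 0"):
            substitute_tokens(text, {"V": "v"})

    def test_single_pass_output_is_a_fixed_point(self):
        """Substituted output contains no tokens, so re-running is identity."""
        out = substitute_tokens(WORKED_SNIPPET, WORKED_TABLE)
        assert "$(" not in out
        assert substitute_tokens(out, WORKED_TABLE) == out

    def test_symbol_table_renders_constants(self):
        t = SymbolTable({"g": 0.25, "V": "V_arr[id]"})
        assert t["g"] == "0.25"
        assert t["V"] == "V_arr[id]"
        with pytest.raises(SnippetError):
            t.define("g", 0.5)  # injective on names

    def test_referenced_tokens(self):
        assert referenced_tokens(WORKED_SNIPPET) == {"V", "g", "C", "Isyn"}


def _single_pop(template, params, init, n=1, dt=1.0):
    m = NNModel("t", dt=dt)
    pop = m.add_neuron_population("P", n, template, params, init)
    return m, pop


class TestNeuronRoutines:
    def test_leaky_integrator_euler_step(self):
        # hand evaluation: V <- V + (-g/C*V + 0) * 1 = -10 + 2 = -8
        m, pop = _single_pop(bm.leaky_integrator(), [0.2, 1.0], [-10.0])
        sim, thr, rst = build_neuron_routines(pop, m.dt)
        S = pop.initial_state(np.float64)
        sim.entry(S, np.zeros(1), np.full(1, -1e10), 0.0, np.random.default_rng(0))
        assert S["V"][0] == pytest.approx(-8.0)

    def test_threshold_mask(self):
        m, pop = _single_pop(bm.leaky_integrator(), [0.2, 1.0], [0.0], n=3)
        _, thr, _ = build_neuron_routines(pop, m.dt)
        S = {"V": np.array([-1.0, 0.0, 5.0])}
        mask = thr.entry(S, np.zeros(3), np.full(3, -1e10), 0.0, None)
        assert mask.tolist() == [False, True, True]

    def test_reset_applies_only_to_masked_neurons(self):
        m, pop = _single_pop(bm.leaky_integrator(), [0.2, 1.0], [0.0], n=3)
        _, _, rst = build_neuron_routines(pop, m.dt)
        S = {"V": np.array([5.0, 7.0, 9.0])}
        rst.entry(S, np.zeros(3), np.full(3, -1e10), np.array([1, 2]), 0.0, None)
        assert S["V"].tolist() == [5.0, -60.0, -60.0]

    def test_generated_source_is_deterministic(self):
        m, pop = _single_pop(bm.izhikevich(), [0.02, 0.2],
                             [-65.0, -13.0, -65.0, 8.0])
        a = build_neuron_routines(pop, m.dt)
        b = build_neuron_routines(pop, m.dt)
        for ra, rb in zip(a, b):
            assert ra.source_text == rb.source_text

    def test_unresolved_token_reports_token_and_kind(self):
        bad = NeuronModel("bad", ("V",), ("double",), sim_code="$(V) += $(W);")
        m, pop = _single_pop(bad, [], [0.0])
        with pytest.raises(SnippetError, match=r"\$\(W\).*sim"):
            build_neuron_routines(pop, m.dt)

    def test_derived_parameter_enters_code_as_constant(self):
        m, pop = _single_pop(bm.leaky_integrator(use_derived=True),
                             [0.2, 1.0], [-10.0])
        sim, _, _ = build_neuron_routines(pop, m.dt)
        assert "0.2" in sim.source_text
        S = pop.initial_state(np.float64)
        sim.entry(S, np.zeros(1), np.full(1, -1e10), 0.0, None)
        assert S["V"][0] == pytest.approx(-8.0)


def _two_pop_projection(weight_model, postsyn_model, n_pre=2, n_post=1,
                        mode="individual", weight_init=(0.1,),
                        weight_params=(), postsyn_params=(), dt=1.0):
    m = NNModel("t", dt=dt)
    m.add_neuron_population("A", n_pre, bm.leaky_integrator(), [0.2, 1.0], [-70.0])
    m.add_neuron_population("B", n_post, bm.leaky_integrator(), [0.2, 1.0], [-70.0])
    sp = m.add_synapse_population("AB", "A", "B", weight_model, "dense", mode, 0,
                                  postsyn_model,
                                  weight_params=list(weight_params),
                                  weight_init_vars=list(weight_init),
                                  postsyn_params=list(postsyn_params))
    return m, sp


class TestSynapseRoutines:
    def test_pulse_spikes_accumulate_additively(self):
        # two spiking pre neurons, g = 0.1 each, one shared target -> +0.2
        m, sp = _two_pop_projection(bm.pulse_synapse(), bm.delta_current())
        routines = build_synapse_routines(sp, m.dt)
        inSyn = np.zeros(1)
        gather = sp.built_projection().gather_rows(np.array([0, 1]))
        syn_vars = {"g": np.full(2, 0.1)}
        routines["sim"].entry(syn_vars, {"V": np.zeros(2)}, {"V": np.zeros(1)},
                              inSyn, np.zeros(2), np.zeros(1), *gather, 0.0, None)
        assert inSyn[0] == pytest.approx(0.2)

    def test_empty_synapse_dynamics_generates_no_routine(self):
        m, sp = _two_pop_projection(bm.pulse_synapse(), bm.delta_current())
        routines = build_synapse_routines(sp, m.dt)
        assert routines["dynamics"] is None
        assert routines["evnt"] is None and routines["evnt_threshold"] is None

    def test_event_threshold_mask_over_pre_population(self):
        m, sp = _two_pop_projection(bm.graded_synapse(), bm.exp_decay_current(),
                                    mode="global", weight_init=(0.5,),
                                    weight_params=(-30.0, 10.0),
                                    postsyn_params=(1.0,))
        routines = build_synapse_routines(sp, m.dt)
        S = {"V": np.array([-60.0, -10.0])}
        mask = routines["evnt_threshold"].entry(S, None, np.zeros(2), 0.0, None)
        assert mask.tolist() == [False, True]
        # all pre subthreshold -> empty event set
        S = {"V": np.array([-60.0, -60.0])}
        mask = routines["evnt_threshold"].entry(S, None, np.zeros(2), 0.0, None)
        assert not mask.any()


class TestPostSynRoutines:
    def test_identity_apply_input(self):
        m, sp = _two_pop_projection(bm.pulse_synapse(), bm.delta_current(),
                                    n_post=3)
        apply_input, decay = build_postsyn_routines(sp, m.dt)
        inSyn = np.array([0.0, 1.0, 2.0])
        Isyn = np.zeros(3)
        apply_input.entry({}, {"V": np.zeros(3)}, inSyn, Isyn, 0.0, None)
        assert Isyn.tolist() == [0.0, 1.0, 2.0]
        decay.entry({}, {"V": np.zeros(3)}, inSyn, 0.0, None)
        assert inSyn.tolist() == [0.0, 0.0, 0.0]  # delta pulse clears

    def test_exponential_decay_closed_form(self):
        # tau = 1 ms, DT = 1 ms: one decay step multiplies by e^-1
        m, sp = _two_pop_projection(bm.pulse_synapse(), bm.exp_decay_current(),
                                    postsyn_params=(1.0,))
        _, decay = build_postsyn_routines(sp, m.dt)
        inSyn = np.array([1.0])
        decay.entry({}, {"V": np.zeros(1)}, inSyn, 0.0, None)
        assert inSyn[0] == pytest.approx(np.exp(-1.0), rel=1e-15)

    def test_contributions_from_multiple_projections_sum(self):
        m = NNModel("t", dt=1.0)
        m.add_neuron_population("A", 1, bm.leaky_integrator(), [0.2, 1.0], [-70.0])
        m.add_neuron_population("B", 1, bm.leaky_integrator(), [0.2, 1.0], [-70.0])
        m.add_neuron_population("C", 1, bm.leaky_integrator(), [0.2, 1.0], [-70.0])
        sps = [m.add_synapse_population(nm, src, "C", bm.pulse_synapse(),
                                        "dense", "individual", 0, bm.delta_current(),
                                        weight_init_vars=[0.1])
               for nm, src in (("AC", "A"), ("BC", "B"))]
        Isyn = np.zeros(1)
        for sp, contrib in zip(sps, (0.5, 0.25)):
            apply_input, _ = build_postsyn_routines(sp, m.dt)
            apply_input.entry({}, {"V": np.zeros(1)}, np.array([contrib]),
                              Isyn, 0.0, None)
        assert Isyn[0] == pytest.approx(0.75)

    def test_assigning_a_constant_is_rejected(self):
        bad = NeuronModel("bad", ("V",), ("double",), param_names=("g",),
                          sim_code="$(g) = 1.0;")
        m = NNModel("t")
        pop = m.add_neuron_population("P", 1, bad, [0.5], [0.0])
        with pytest.raises(SnippetError, match="constant"):
            build_neuron_routines(pop, m.dt)
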