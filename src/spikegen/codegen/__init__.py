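"""Code generation: snippet text -> executable vectorized update routines.

The pipeline mirrors the declarative workflow of the framework: a model
template carries code snippets with ``$()`` tokens; a :class:`SymbolTable`
resolves every token to its storage expression (state-array element,
parameter constant, or predefined symbol such as ``Isyn``, ``DT``, ``t``,
``id``, ``inSyn``); and the emitter synthesizes the source of one Python
routine per (population, snippet kind), compiled once at simulation setup.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .parser import SnippetError, parse_expression, parse_statements, referenced_tokens
from .emit import (
    FUNCTIONS,
    RANDOM_FUNCTIONS,
    GeneratedRoutine,
    Sym,
    SymbolTable,
    emit_routine,
    substitute_tokens,
)

__all__ = [
    "SnippetError",
    "SymbolTable",
    "Sym",
    "GeneratedRoutine",
    "substitute_tokens",
    "referenced_tokens",
    "build_neuron_routines",
    "build_synapse_routines",
    "build_postsyn_routines",
    "neuron_symbol_table",
    "weight_symbol_table",
    "postsyn_symbol_table",
    "FUNCTIONS",
    "RANDOM_FUNCTIONS",
]


def _dtype(precision: str):
    return np.float32 if precision == "single" else np.float64


# ---------------------------------------------------------------- symbol tables


def neuron_symbol_table(
    template, params: Mapping[str, float], dt: float, *, gathered: bool = False
) -> SymbolTable:
    """Symbols visible to a neuron model's snippets.

    ``gathered=True`` builds the reset-context table, where state arrays are
    addressed through the spiking-neuron index vector ``_ids``.
    """
    t = SymbolTable()
    idx = "[_ids]" if gathered else ""
    for name in template.var_names:
        store = (
            f"S[{name!r}][_ids] = {{v}}"
            if gathered
            else f"S[{name!r}] = _wb({{v}}, S[{name!r}])"
        )
        t.define(name, Sym("array", load=f"S[{name!r}]{idx}", store=store))
    for name, value in params.items():
        t.define(name, Sym("const", value=value))
    t.define("Isyn", Sym("array", load=f"Isyn{idx}"))
    t.define("sT", Sym("array", load=f"sT{idx}"))
    t.define("DT", Sym("const", value=dt))
    t.define("t", Sym("scalar", load="_t"))
    t.define("id", Sym("array", load="_ids" if gathered else "_np.arange(_n)"))
    return t


def weight_symbol_table(
    syn_pop, params: Mapping[str, float], dt: float
) -> SymbolTable:
    """Symbols visible to weight-update snippets (Table-1 style code)."""
    t = SymbolTable()
    wm = syn_pop.weight_model
    if syn_pop.conductance_mode == "global":
        for name, value in zip(wm.var_names, syn_pop.weight_init_var_values):
            t.define(name, Sym("const", value=float(value)))
    else:
        for name in wm.var_names:
            t.define(
                name,
                Sym("array", load=f"SV[{name!r}][_syn]", store=f"SV[{name!r}][_syn] = {{v}}"),
            )
    for name, value in params.items():
        t.define(name, Sym("const", value=value))
    for name in syn_pop.pre.model.var_names:
        t.define(f"{name}_pre", Sym("array", load=f"PRE[{name!r}][_pre]"))
    for name in syn_pop.post.model.var_names:
        if f"{name}_post" not in t:
            t.define(f"{name}_post", Sym("array", load=f"POST[{name!r}][_post]"))
    t.define("sT_pre", Sym("array", load="sTpre[_pre]"))
    t.define("sT_post", Sym("array", load="sTpost[_post]"))
    t.define("inSyn", Sym("array", load="inSyn[_post]"))
    t.define("DT", Sym("const", value=dt))
    t.define("t", Sym("scalar", load="_t"))
    return t


def event_symbol_table(syn_pop, params: Mapping[str, float], dt: float) -> SymbolTable:
    """Symbols for the pre-synaptic event threshold (full pre-population view)."""
    t = SymbolTable()
    wm = syn_pop.weight_model
    if syn_pop.conductance_mode == "global":
        for name, value in zip(wm.var_names, syn_pop.weight_init_var_values):
            t.define(name, Sym("const", value=float(value)))
    for name, value in params.items():
        t.define(name, Sym("const", value=value))
    for name in syn_pop.pre.model.var_names:
        t.define(f"{name}_pre", Sym("array", load=f"S[{name!r}]"))
    t.define("sT_pre", Sym("array", load="sT"))
    t.define("DT", Sym("const", value=dt))
    t.define("t", Sym("scalar", load="_t"))
    return t


def postsyn_symbol_table(
    syn_pop, params: Mapping[str, float], dt: float, *, decay: bool
) -> SymbolTable:
    """Symbols for post-synaptic model snippets (apply-input / decay)."""
    t = SymbolTable()
    pm = syn_pop.postsyn_model
    for name in pm.var_names:
        t.define(name, Sym("array", load=f"PV[{name!r}]", store=f"PV[{name!r}] = _wb({{v}}, PV[{name!r}])"))
    for name, value in params.items():
        t.define(name, Sym("const", value=value))
    if decay:
        t.define("inSyn", Sym("array", load="inSyn", store="inSyn[...] = {v}"))
    else:
        t.define("inSyn", Sym("array", load="inSyn"))
        t.define("Isyn", Sym("array", load="Isyn", store="Isyn[...] = {v}"))
    for name in syn_pop.post.model.var_names:
        if name not in t:
            t.define(name, Sym("array", load=f"POST[{name!r}]"))
    t.define("DT", Sym("const", value=dt))
    t.define("t", Sym("scalar", load="_t"))
    t.define("id", Sym("array", load="_np.arange(_n)"))
    return t


# ---------------------------------------------------------------- builders

_NEURON_ARGS = "S, Isyn, sT, _t, _rng"
_RESET_ARGS = "S, Isyn, sT, _ids, _t, _rng"
_WEIGHT_ARGS = "SV, PRE, POST, inSyn, sTpre, sTpost, _syn, _pre, _post, _t, _rng"
_APPLY_ARGS = "PV, POST, inSyn, Isyn, _t, _rng"
_DECAY_ARGS = "PV, POST, inSyn, _t, _rng"


def build_neuron_routines(population, model_dt: float, precision: str = "double"):
    """Synthesize (sim, threshold, reset) routines for one neuron population.

    ``sim`` advances all state variables of all neurons by one global step;
    ``threshold`` returns the boolean spike mask; ``reset`` is applied
    elementwise to exactly the masked neurons after threshold evaluation.
    Empty snippets yield ``None`` entries.
    """
    tmpl = population.model
    params = population.param_map(model_dt)
    dtype = _dtype(precision)
    table = neuron_symbol_table(tmpl, params, model_dt)
    sim = threshold = reset = None
    if tmpl.sim_code.strip():
        sim = emit_routine(
            tmpl.sim_code, table, "sim", population.name,
            args=_NEURON_ARGS, n_expr="Isyn.shape[0]", dtype=dtype,
        )
    if tmpl.threshold_condition_code.strip():
        threshold = emit_routine(
            tmpl.threshold_condition_code, table, "threshold", population.name,
            args=_NEURON_ARGS, n_expr="Isyn.shape[0]", expression=True, dtype=dtype,
        )
    if tmpl.reset_code.strip():
        rtable = neuron_symbol_table(tmpl, params, model_dt, gathered=True)
        reset = emit_routine(
            tmpl.reset_code, rtable, "reset", population.name,
            args=_RESET_ARGS, n_expr="_ids.size", dtype=dtype,
        )
    return sim, threshold, reset


def build_synapse_routines(syn_pop, model_dt: float, precision: str = "double"):
    """Synthesize the weight-update routines for one synapse population.

    Returns a dict with keys ``sim`` (on pre-synaptic spike), ``evnt`` (on
    pre-synaptic event), ``evnt_threshold`` (event condition over the pre
    population), ``learn`` (on post-synaptic spike) and ``dynamics`` (every
    step); absent snippets map to ``None``.
    """
    wm = syn_pop.weight_model
    params = syn_pop.weight_param_map(model_dt)
    dtype = _dtype(precision)
    table = weight_symbol_table(syn_pop, params, model_dt)
    out: dict[str, GeneratedRoutine | None] = {
        "sim": None, "evnt": None, "evnt_threshold": None, "learn": None, "dynamics": None,
    }
    name = syn_pop.name

    def _stmts(snippet, kind):
        return emit_routine(
            snippet, table, kind, name,
            args=_WEIGHT_ARGS, n_expr="_syn.size",
            acc_index="_post", acc_target="inSyn", dtype=dtype,
        )

    if wm.sim_code.strip():
        out["sim"] = _stmts(wm.sim_code, "simCode")
    if wm.sim_code_evnt.strip():
        out["evnt"] = _stmts(wm.sim_code_evnt, "simCodeEvnt")
    if wm.sim_learn_post.strip():
        out["learn"] = _stmts(wm.sim_learn_post, "simLearnPost")
    if wm.synapse_dynamics.strip():
        out["dynamics"] = _stmts(wm.synapse_dynamics, "synapseDynamics")
    if wm.evnt_threshold.strip():
        etable = event_symbol_table(syn_pop, params, model_dt)
        out["evnt_threshold"] = emit_routine(
            wm.evnt_threshold, etable, "evntThreshold", name,
            args=_NEURON_ARGS, n_expr="sT.shape[0]", expression=True, dtype=dtype,
        )
    return out


def build_postsyn_routines(syn_pop, model_dt: float, precision: str = "double"):
    """Synthesize (apply_input, decay) routines for one synapse population.

    ``apply_input`` adds the projection's contribution to the target
    population's summed input ``Isyn``; ``decay`` updates the activation
    accumulator ``inSyn`` in place once per step.
    """
    pm = syn_pop.postsyn_model
    params = syn_pop.postsyn_param_map(model_dt)
    dtype = _dtype(precision)
    name = syn_pop.name
    if not pm.apply_input_code.strip():
        raise SnippetError(f"post-synaptic model {pm.name!r} has empty apply-input code")
    apply_input = emit_routine(
        pm.apply_input_code,
        postsyn_symbol_table(syn_pop, params, model_dt, decay=False),
        "applyInput", name,
        args=_APPLY_ARGS, n_expr="inSyn.shape[0]", dtype=dtype,
    )
    decay = None
    if pm.decay_code.strip():
        decay = emit_routine(
            pm.decay_code,
            postsyn_symbol_table(syn_pop, params, model_dt, decay=True),
            "decay", name,
            args=_DECAY_ARGS, n_expr="inSyn.shape[0]", dtype=dtype,
        )
    return apply_input, decay
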