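"""Built-in model templates and their scalar reference implementations.

Every built-in is an ordinary snippet-bearing template — defined exactly like
a user model — so these double as worked examples.  Alongside each template
this module provides plain host-level reference functions (single neuron /
single synapse, scalar math) that serve as independent oracles for the
generated vectorized code.

Units follow common practice for point-neuron models: membrane potential in
mV, time in ms, conductances in uS, currents in nA, capacitance in nF.
"""

from __future__ import annotations

import math
import os
from typing import Mapping

import numpy as np

from .model import NeuronModel, PostSynapticModel, WeightUpdateModel

__all__ = [
    "leaky_integrator",
    "izhikevich",
    "izhikevich_thalamic",
    "izhikevich_variable",
    "traub_miles",
    "poisson",
    "pulse_synapse",
    "graded_synapse",
    "stdp_synapse",
    "exp_decay_current",
    "exp_cond",
    "delta_current",
    "TRAUB_MILES_PARAMS",
    "izhikevich_step_reference",
    "traub_miles_step_reference",
    "hh_rates_safe",
    "hh_rest_state",
    "stdp_kernel",
    "stdp_update",
    "snippet_set",
    "write_snippets",
]


# ---------------------------------------------------------------- neuron models


def leaky_integrator(use_derived: bool = False) -> NeuronModel:
    """Linear forward-Euler leaky integrator (the canonical worked example).

    dV/dt = (-g/C) V + Isyn; spikes when V crosses 0 mV, resetting to -60 mV.
    With ``use_derived=True`` the ratio g/C enters the code as a derived
    parameter ``a`` precomputed at initialisation.
    """
    if use_derived:
        return NeuronModel(
            name="LeakyIntegratorDerived",
            var_names=("V",), var_types=("double",),
            param_names=("g", "C"),
            derived_params=(("a", lambda p, dt: p["g"] / p["C"]),),
            sim_code="$(V) += (-$(a)*$(V) + $(Isyn))*DT;",
            threshold_condition_code="$(V) >= 0.0",
            reset_code="$(V) = -60.0;",
        )
    return NeuronModel(
        name="LeakyIntegrator",
        var_names=("V",), var_types=("double",),
        param_names=("g", "C"),
        sim_code="$(V) += (-$(g)/$(C)*$(V) + $(Isyn))*DT;",
        threshold_condition_code="$(V) >= 0.0",
        reset_code="$(V) = -60.0;",
    )


_IZH_BODY = """\
{inp}
$(v) += 0.5*(0.04*$(v)*$(v) + 5.0*$(v) + 140.0 - $(u) + {cur})*DT;
$(v) += 0.5*(0.04*$(v)*$(v) + 5.0*$(v) + 140.0 - $(u) + {cur})*DT;
$(u) += $(a)*($(b)*$(v) - $(u))*DT;
"""


def izhikevich() -> NeuronModel:
    """Izhikevich neuron: v' = 0.04 v^2 + 5v + 140 - u + I, u' = a(bv - u).

    The fast variable v takes two half-steps of DT/2 per global step (for
    numerical stability at DT = 1 ms); u takes one full DT step.  Spike at
    v >= 30 mV, reset v = c and u += d.  The reset value c and the recovery
    increment d are per-neuron variables so heterogeneous populations can be
    expressed with per-neuron initial values.
    """
    return NeuronModel(
        name="Izhikevich",
        var_names=("v", "u", "c", "d"),
        var_types=("double",) * 4,
        param_names=("a", "b"),
        sim_code=_IZH_BODY.format(inp="", cur="$(Isyn)"),
        threshold_condition_code="$(v) >= 30.0",
        reset_code="$(v) = $(c); $(u) += $(d);",
    )


def izhikevich_thalamic() -> NeuronModel:
    """Izhikevich neuron with fresh normal 'thalamic' input each step.

    The injected current is Isyn + sigma * N(0, 1), drawn per neuron per
    step and held fixed across the two half-steps, as in the stochastic
    thalamic drive of the pulse-coupled benchmark network.
    """
    return NeuronModel(
        name="IzhikevichThalamic",
        var_names=("v", "u", "c", "d"),
        var_types=("double",) * 4,
        param_names=("a", "b", "sigma"),
        sim_code=_IZH_BODY.format(
            inp="inp = $(Isyn) + $(sigma)*normal();", cur="inp"),
        threshold_condition_code="$(v) >= 30.0",
        reset_code="$(v) = $(c); $(u) += $(d);",
    )


def izhikevich_variable() -> NeuronModel:
    """Izhikevich neuron with all of a, b, c, d as per-neuron variables."""
    return NeuronModel(
        name="IzhikevichVariable",
        var_names=("v", "u", "a", "b", "c", "d"),
        var_types=("double",) * 6,
        param_names=("sigma",),
        sim_code=_IZH_BODY.format(
            inp="inp = $(Isyn) + $(sigma)*normal();", cur="inp"),
        threshold_condition_code="$(v) >= 30.0",
        reset_code="$(v) = $(c); $(u) += $(d);",
    )


#: Traub-Miles Hodgkin-Huxley parameters (uS, mV, nF), canonical values of
#: the cited single-compartment reduction.
TRAUB_MILES_PARAMS: dict[str, float] = {
    "gNa": 7.15, "ENa": 50.0,
    "gK": 1.43, "EK": -95.0,
    "gl": 0.02672, "El": -63.563,
    "Cmem": 0.143,
}

# x/(exp(x)-1) has a removable singularity at x=0; inside |x| < 1e-6 the code
# switches to the analytic limit 1 - x/2 (the l'Hopital value plus the linear
# series term), which matches the raw formula to ~1e-13 relative at the seam.
_SAFE = "((abs({x}) < 1.0e-6) ? (1.0 - {x}/2.0) : ({x} / (exp({x}) - 1.0)))"

_TM_SIM = f"""\
$(preV) = $(V);
for (i = 0; i < 5; i++) {{
    Imem = -($(m)*$(m)*$(m)*$(h)*$(gNa)*($(V)-$(ENa))
           + $(n)*$(n)*$(n)*$(n)*$(gK)*($(V)-$(EK))
           + $(gl)*($(V)-$(El)) - $(Isyn));
    x = (-52.0 - $(V)) / 4.0;
    a = 1.28 * {_SAFE.format(x='x')};
    y = ($(V) + 25.0) / 5.0;
    b = 1.4 * {_SAFE.format(x='y')};
    $(m) += (a*(1.0 - $(m)) - b*$(m)) * (DT/5.0);
    a = 0.128 * exp((-48.0 - $(V))/18.0);
    b = 4.0 / (exp((-25.0 - $(V))/5.0) + 1.0);
    $(h) += (a*(1.0 - $(h)) - b*$(h)) * (DT/5.0);
    z = (-50.0 - $(V)) / 5.0;
    a = 0.16 * {_SAFE.format(x='z')};
    b = 0.5 * exp((-55.0 - $(V))/40.0);
    $(n) += (a*(1.0 - $(n)) - b*$(n)) * (DT/5.0);
    $(V) += Imem/$(Cmem) * (DT/5.0);
}}
"""


def traub_miles() -> NeuronModel:
    """Traub-Miles Hodgkin-Huxley neuron.

    Five forward-Euler sub-steps of DT/5 per global step; the rate functions
    guard their removable singularities with the analytic limit.  A spike is
    the rising crossing of 0 mV, detected with the previous-step voltage
    ``preV`` (no engine-level edge detection or refractory mechanism).
    """
    return NeuronModel(
        name="TraubMilesHH",
        var_names=("V", "m", "h", "n", "preV"),
        var_types=("double",) * 5,
        param_names=tuple(TRAUB_MILES_PARAMS),
        sim_code=_TM_SIM,
        threshold_condition_code="$(V) >= 0.0 && $(preV) < 0.0",
        reset_code="",
    )


def poisson() -> NeuronModel:
    """Poisson spike source with a refractory gap.

    Each step draws u ~ U(0,1) per neuron; a spike is emitted when
    u < rate * DT (rate in Hz, DT in ms) and the last spike is at least
    ``trefract`` ms in the past.  The rate is a per-neuron variable so input
    patterns can be switched during a protocol.
    """
    return NeuronModel(
        name="PoissonSource",
        var_names=("u", "rateHz"),
        var_types=("double", "double"),
        param_names=("trefract",),
        sim_code="$(u) = uniform();",
        threshold_condition_code=(
            "$(u) < $(rateHz) * DT / 1000.0 && $(t) - $(sT) >= $(trefract)"
        ),
        reset_code="",
    )


# ---------------------------------------------------------------- synapse models


def pulse_synapse() -> WeightUpdateModel:
    """Simple conductance pulse: each pre-synaptic spike adds the weight g
    to the target's post-synaptic activation."""
    return WeightUpdateModel(
        name="PulseSynapse",
        var_names=("g",), var_types=("double",),
        sim_code="addtoinSyn = $(g);",
    )


def graded_synapse() -> WeightUpdateModel:
    """Graded synapse: transmits continuously while the pre-synaptic voltage
    is above ``Epre``, adding g * tanh((V_pre - Epre)/Vslope) * DT per step."""
    return WeightUpdateModel(
        name="GradedSynapse",
        var_names=("g",), var_types=("double",),
        param_names=("Epre", "Vslope"),
        evnt_threshold="$(V_pre) > $(Epre)",
        sim_code_evnt=(
            "addtoinSyn = $(g) * tanh(($(V_pre) - $(Epre)) / $(Vslope)) * DT;"
        ),
    )


_STDP_PRE = """\
addtoinSyn = $(g);
dt = $(sT_post) - $(t);
dg = ((dt >= -$(tminus)) && (dt < 0.0)) ? (-$(aminus)*(1.0 + dt/$(tminus))) : 0.0;
$(g) = fmax($(gmin), fmin($(gmax), $(g) + dg));
"""

_STDP_POST = """\
dt = $(t) - $(sT_pre);
dg = ((dt >= 0.0) && (dt <= $(tplus))) ? ($(aplus)*(1.0 - dt/$(tplus))) : (-$(adep));
$(g) = fmax($(gmin), fmin($(gmax), $(g) + dg));
"""


def stdp_synapse() -> WeightUpdateModel:
    """Primitive STDP learning synapse with a piecewise-linear pair kernel.

    On a pre-synaptic spike the weight g is transmitted and depressed if the
    post-synaptic neuron fired within the preceding ``tminus`` ms; on a
    post-synaptic spike the weight is potentiated if the pre-synaptic neuron
    fired within the preceding ``tplus`` ms.  The pair change is linear in
    the spike-time difference (peak ``aplus`` at coincidence, peak
    ``-aminus`` just after a post-before-pre pairing; see
    :func:`stdp_kernel`).

    ``adep`` adds the non-Hebbian term of the primitive olfactory learning
    rule: every post-synaptic spike also depresses each incoming synapse
    whose pre-synaptic neuron did *not* fire within ``tplus``, so synapses
    uncorrelated with the post-synaptic cell lose out against coincident
    ones.  Set it to 0 for a pure pair-based rule.

    The weight is hard-clamped to [gmin, gmax] after every update.  Spike
    times come from the engine-maintained variables ``sT_pre`` / ``sT_post``.
    """
    return WeightUpdateModel(
        name="STDPSynapse",
        var_names=("g",), var_types=("double",),
        param_names=("aplus", "aminus", "adep", "tplus", "tminus", "gmin", "gmax"),
        sim_code=_STDP_PRE,
        sim_learn_post=_STDP_POST,
    )


# ---------------------------------------------------------------- post-synaptic models


def _exp_decay(p: Mapping[str, float], dt: float | None) -> float:
    if dt is None:
        raise ValueError("expDecay needs the global time step")
    return math.exp(-dt / p["tau"])


def exp_decay_current() -> PostSynapticModel:
    """Exponentially decaying current: Isyn += inSyn; inSyn *= exp(-DT/tau).

    The decay factor is a derived parameter computed once at initialisation.
    """
    return PostSynapticModel(
        name="ExpDecayCurrent",
        param_names=("tau",),
        derived_params=(("expDecay", _exp_decay),),
        apply_input_code="$(Isyn) += $(inSyn);",
        decay_code="$(inSyn) *= $(expDecay);",
    )


def exp_cond() -> PostSynapticModel:
    """Exponentially decaying conductance with reversal potential E:
    Isyn += inSyn * (E - V), where V is the target neuron's voltage."""
    return PostSynapticModel(
        name="ExpCond",
        param_names=("tau", "E"),
        derived_params=(("expDecay", _exp_decay),),
        apply_input_code="$(Isyn) += $(inSyn) * ($(E) - $(V));",
        decay_code="$(inSyn) *= $(expDecay);",
    )


def delta_current() -> PostSynapticModel:
    """Instantaneous current pulse: the accumulated activation is applied as
    input once and then cleared (the delta-pulse coupling of the
    pulse-coupled Izhikevich network)."""
    return PostSynapticModel(
        name="DeltaCurrent",
        apply_input_code="$(Isyn) += $(inSyn);",
        decay_code="$(inSyn) = 0.0;",
    )


# ---------------------------------------------------------------- scalar oracles


def izhikevich_step_reference(v, u, a, b, I, dt: float = 1.0):
    """One global step of the Izhikevich model for a single neuron.

    Two half-steps for v, then one full step for u; returns (v, u, spiked)
    where ``spiked`` reports v >= 30 mV after the update.  The caller applies
    the reset (v = c, u += d) exactly as the engine does.
    """
    v = v + 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + I) * dt
    v = v + 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + I) * dt
    u = u + a * (b * v - u) * dt
    return v, u, v >= 30.0


def _x_over_expm1(x):
    """x / (exp(x) - 1) with the removable singularity at 0 filled by its
    limit (switching to 1 - x/2 for |x| < 1e-6)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1.0e-6
    safe = np.where(small, 1.0, x)
    with np.errstate(all="ignore"):
        raw = safe / np.expm1(safe)
    return np.where(small, 1.0 - x / 2.0, raw)


def hh_rates_safe(V):
    """Singularity-safe Traub-Miles rate functions.

    Returns a dict with alpha/beta for the gating variables m, h, n, finite
    for every finite V including the removable singularities at V = -52 mV
    (alpha_m), V = -25 mV (beta_m) and V = -50 mV (alpha_n).
    """
    V = np.asarray(V, dtype=float)
    return {
        "alpha_m": 1.28 * _x_over_expm1((-52.0 - V) / 4.0),
        "beta_m": 1.4 * _x_over_expm1((V + 25.0) / 5.0),
        "alpha_h": 0.128 * np.exp((-48.0 - V) / 18.0),
        "beta_h": 4.0 / (np.exp((-25.0 - V) / 5.0) + 1.0),
        "alpha_n": 0.16 * _x_over_expm1((-50.0 - V) / 5.0),
        "beta_n": 0.5 * np.exp((-55.0 - V) / 40.0),
    }


def hh_rest_state(V: float | None = None) -> dict[str, float]:
    """Steady-state gating values at voltage V (default: leak reversal)."""
    if V is None:
        V = TRAUB_MILES_PARAMS["El"]
    r = hh_rates_safe(V)
    return {
        "V": float(V),
        "m": float(r["alpha_m"] / (r["alpha_m"] + r["beta_m"])),
        "h": float(r["alpha_h"] / (r["alpha_h"] + r["beta_h"])),
        "n": float(r["alpha_n"] / (r["alpha_n"] + r["beta_n"])),
    }


def traub_miles_step_reference(V, m, h, n, Isyn, params=None, dt: float = 0.2,
                               substeps: int = 5):
    """One global step of the Traub-Miles neuron (scalar forward Euler with
    ``substeps`` inner steps), mirroring the template's sim code."""
    p = dict(TRAUB_MILES_PARAMS if params is None else params)
    sdt = dt / substeps
    for _ in range(substeps):
        Imem = -(
            m ** 3 * h * p["gNa"] * (V - p["ENa"])
            + n ** 4 * p["gK"] * (V - p["EK"])
            + p["gl"] * (V - p["El"])
            - Isyn
        )
        r = hh_rates_safe(V)
        m = m + (r["alpha_m"] * (1.0 - m) - r["beta_m"] * m) * sdt
        h = h + (r["alpha_h"] * (1.0 - h) - r["beta_h"] * h) * sdt
        n = n + (r["alpha_n"] * (1.0 - n) - r["beta_n"] * n) * sdt
        V = V + Imem / p["Cmem"] * sdt
    return float(V), float(m), float(h), float(n)


def stdp_kernel(delta_t, params: Mapping[str, float]):
    """Weight change for a pre/post spike pair separated by
    ``delta_t = t_post - t_pre`` (ms), before clamping.

    Piecewise linear: peak potentiation ``aplus`` at coincidence decaying to
    zero at ``tplus``; depression of peak ``aminus`` for post-before-pre
    pairings within ``tminus``; zero outside the kernel support.
    """
    dt = np.asarray(delta_t, dtype=float)
    pot = np.where((dt >= 0.0) & (dt <= params["tplus"]),
                   params["aplus"] * (1.0 - dt / params["tplus"]), 0.0)
    dep = np.where((dt >= -params["tminus"]) & (dt < 0.0),
                   -params["aminus"] * (1.0 + dt / params["tminus"]), 0.0)
    out = pot + dep
    return float(out) if out.shape == () else out


def stdp_update(delta_t, params: Mapping[str, float], g=None):
    """STDP update for one spike pair.

    With ``g`` given, returns the new weight clamped to [gmin, gmax];
    without it, returns the raw kernel change.
    """
    dg = stdp_kernel(delta_t, params)
    if g is None:
        return dg
    return np.clip(g + dg, params["gmin"], params["gmax"])


# ---------------------------------------------------------------- snippet export


def snippet_set(template) -> dict[str, str]:
    """The template's plain-text snippet set (field name -> code)."""
    fields = (
        "sim_code", "threshold_condition_code", "reset_code",
        "sim_code_evnt", "sim_learn_post", "synapse_dynamics", "evnt_threshold",
        "apply_input_code", "decay_code",
    )
    return {f: getattr(template, f) for f in fields
            if getattr(template, f, "") and getattr(template, f).strip()}


def write_snippets(template, directory: str) -> list[str]:
    """Dump each snippet of ``template`` to ``<name>_<kind>.txt``."""
    os.makedirs(directory, exist_ok=True)
    written = []
    for kind, text in snippet_set(template).items():
        path = os.path.join(directory, f"{template.name}_{kind}.txt")
        with open(path, "w") as fh:
            fh.write(text)
        written.append(path)
    return written
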