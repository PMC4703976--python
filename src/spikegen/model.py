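"""Declarative network definition.

A network is an :class:`NNModel`: an ordered collection of neuron populations
and synapse populations, a global time step ``dt`` (ms), a floating-point
precision and an RNG seed.  Populations instantiate snippet-bearing model
templates (:class:`NeuronModel`, :class:`WeightUpdateModel`,
:class:`PostSynapticModel`) with concrete parameter values and initial state.

Parameters are numbers fixed for the whole simulation and shared across a
population; quantities that vary across neurons (or over time) are variables,
initialised uniformly from a scalar or heterogeneously from a length-``n``
array.  Derived parameters are computed once from the primitive parameters at
initialisation (e.g. a decay factor ``exp(-DT/tau)``) and enter the generated
code as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import codegen
from .codegen import SnippetError
from . import connectivity as conn

__all__ = [
    "NeuronModel",
    "WeightUpdateModel",
    "PostSynapticModel",
    "NeuronPopulation",
    "SynapsePopulation",
    "NNModel",
    "Diagnostic",
    "ModelDefinitionError",
    "compute_derived_parameters",
    "add_neuron_population",
    "add_synapse_population",
    "validate_model",
]

VAR_TYPES = ("single", "double", "integer")

#: transform over primitive parameters: fn(params, dt) -> value
DerivedParam = tuple[str, Callable[[Mapping[str, float], float | None], float]]


class ModelDefinitionError(ValueError):
    """A model-definition contract violation, naming the offending field."""


@dataclass(frozen=True)
class NeuronModel:
    """Snippet-bearing neuron model template.

    ``sim_code`` advances the state by one global step ``DT``; the threshold
    condition is evaluated at every time step and a non-zero value emits a
    spike, upon which ``reset_code`` runs for the spiking neurons.
    """

    name: str
    var_names: tuple[str, ...] = ()
    var_types: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()
    derived_params: tuple[DerivedParam, ...] = ()
    sim_code: str = ""
    threshold_condition_code: str = ""
    reset_code: str = ""

    def __post_init__(self):
        _check_template_names(self)
        if len(self.var_types) != len(self.var_names):
            raise ModelDefinitionError(
                f"{self.name}: var_types length {len(self.var_types)} != "
                f"var_names length {len(self.var_names)}"
            )
        for vt in self.var_types:
            if vt not in VAR_TYPES:
                raise ModelDefinitionError(f"{self.name}: unknown var_type {vt!r}")


@dataclass(frozen=True)
class WeightUpdateModel:
    """Synapse (weight update) model template with the five code snippets:

    ``sim_code`` on pre-synaptic spike, ``sim_code_evnt`` on pre-synaptic
    events defined by ``evnt_threshold``, ``sim_learn_post`` on post-synaptic
    spike, and ``synapse_dynamics`` every step.
    """

    name: str
    var_names: tuple[str, ...] = ()
    var_types: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()
    derived_params: tuple[DerivedParam, ...] = ()
    sim_code: str = ""
    sim_code_evnt: str = ""
    sim_learn_post: str = ""
    synapse_dynamics: str = ""
    evnt_threshold: str = ""

    def __post_init__(self):
        _check_template_names(self)


@dataclass(frozen=True)
class PostSynapticModel:
    """Post-synaptic integration: activation -> input current, plus decay."""

    name: str
    var_names: tuple[str, ...] = ()
    var_types: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()
    derived_params: tuple[DerivedParam, ...] = ()
    apply_input_code: str = ""
    decay_code: str = ""

    def __post_init__(self):
        _check_template_names(self)


def _check_template_names(tmpl) -> None:
    seen = set()
    for kind, names in (("variable", tmpl.var_names), ("parameter", tmpl.param_names),
                        ("derived parameter", [d[0] for d in tmpl.derived_params])):
        for nm in names:
            if nm in seen:
                raise ModelDefinitionError(f"{tmpl.name}: duplicate name {nm!r} ({kind})")
            seen.add(nm)


def compute_derived_parameters(template, param_values, dt: float | None = None) -> list[float]:
    """Evaluate the template's derived-parameter transforms once.

    ``param_values`` supplies one number per primitive parameter.  Transforms
    are host-level callables ``fn(params, dt)``; a transform that raises
    (e.g. division by a zero capacitance) propagates with template context.
    """
    params = _param_dict(template, param_values)
    out = []
    for name, fn in template.derived_params:
        try:
            out.append(float(fn(params, dt)))
        except Exception as e:
            raise ModelDefinitionError(
                f"{template.name}: derived parameter {name!r} failed: {e}"
            ) from e
    return out


def _param_dict(template, param_values) -> dict[str, float]:
    values = list(param_values)
    if len(values) != len(template.param_names):
        raise ModelDefinitionError(
            f"{template.name}: expected {len(template.param_names)} parameter values "
            f"for {list(template.param_names)}, got {len(values)}"
        )
    return {n: float(v) for n, v in zip(template.param_names, values)}


def _full_param_map(template, param_values, dt) -> dict[str, float]:
    params = _param_dict(template, param_values)
    derived = compute_derived_parameters(template, param_values, dt)
    params.update({d[0]: v for d, v in zip(template.derived_params, derived)})
    return params


def _check_init_vars(owner: str, template, init_vars, n: int | None):
    vals = list(init_vars)
    if len(vals) != len(template.var_names):
        raise ModelDefinitionError(
            f"{owner}: expected {len(template.var_names)} initial values for variables "
            f"{list(template.var_names)}, got {len(vals)}"
        )
    out = []
    for nm, v in zip(template.var_names, vals):
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            out.append(arr[()])
        else:
            if n is not None and arr.shape != (n,):
                raise ModelDefinitionError(
                    f"{owner}: initial values for variable {nm!r} must be a scalar or a "
                    f"length-{n} array, got shape {arr.shape}"
                )
            out.append(arr.copy())
    return out


@dataclass
class NeuronPopulation:
    """A population of ``n`` neurons sharing one model template."""

    name: str
    n: int
    model: NeuronModel
    param_values: list[float]
    init_var_values: list
    id_offset: int = 0  # global id of neuron 0, assigned at registration

    def param_map(self, dt: float | None = None) -> dict[str, float]:
        return _full_param_map(self.model, self.param_values, dt)

    def initial_state(self, dtype) -> dict[str, np.ndarray]:
        out = {}
        for nm, vt, v in zip(self.model.var_names, self.model.var_types, self.init_var_values):
            dt_ = np.int64 if vt == "integer" else dtype
            out[nm] = np.full(self.n, v, dtype=dt_) if np.ndim(v) == 0 else np.asarray(v, dtype=dt_).copy()
        return out


@dataclass
class SynapsePopulation:
    """A projection between two neuron populations.

    ``connectivity_kind`` selects dense (all-to-all, optionally masked) or
    sparse (YALE-format) storage; ``conductance_mode`` selects one shared
    value per per-synapse variable (``global``) or per-connection arrays
    (``individual``).  The axonal delay, in whole global steps, is identical
    across all synapses of the population.
    """

    name: str
    pre: NeuronPopulation
    post: NeuronPopulation
    weight_model: WeightUpdateModel
    postsyn_model: PostSynapticModel
    connectivity_kind: str
    conductance_mode: str
    delay_steps: int
    weight_param_values: list[float]
    weight_init_var_values: list
    postsyn_param_values: list[float]
    postsyn_init_var_values: list
    projection: object = None  # SparseProjection / DenseProjection
    syn_var_arrays: dict = field(default_factory=dict)  # name -> flat array (sparse)

    def weight_param_map(self, dt=None):
        return _full_param_map(self.weight_model, self.weight_param_values, dt)

    def postsyn_param_map(self, dt=None):
        return _full_param_map(self.postsyn_model, self.postsyn_param_values, dt)

    def connect(self, pairs, var_values: Mapping[str, Sequence[float]] | None = None):
        """Populate a sparse projection from (pre, post) pairs.

        ``var_values`` optionally maps per-synapse variable names to arrays
        aligned with ``pairs``; they are permuted into the canonical YALE
        order along with the connectivity.
        """
        if self.connectivity_kind != "sparse":
            raise ModelDefinitionError(f"{self.name}: connect() requires sparse connectivity")
        npairs = len(pairs)
        sp, order = conn.build_sparse(
            self.pre.n, self.post.n, pairs, values=np.arange(npairs)
        )
        self.projection = sp
        self.syn_var_arrays = {}
        if var_values:
            if self.conductance_mode == "global":
                raise ModelDefinitionError(
                    f"{self.name}: global conductance mode forbids per-synapse variable arrays"
                )
            for nm, vals in var_values.items():
                if nm not in self.weight_model.var_names:
                    raise ModelDefinitionError(
                        f"{self.name}: unknown per-synapse variable {nm!r}"
                    )
                vals = np.asarray(vals, dtype=float)
                if vals.shape != (npairs,):
                    raise ModelDefinitionError(
                        f"{self.name}: values for {nm!r} must align with pairs"
                    )
                self.syn_var_arrays[nm] = vals[order]
        return sp

    def set_dense_mask(self, mask) -> None:
        if self.connectivity_kind != "dense":
            raise ModelDefinitionError(f"{self.name}: mask requires dense connectivity")
        self.projection = conn.DenseProjection(self.pre.n, self.post.n, mask)

    def built_projection(self):
        """The projection container, building the default dense one lazily."""
        if self.projection is None:
            if self.connectivity_kind == "dense":
                self.projection = conn.DenseProjection(self.pre.n, self.post.n)
            else:
                raise ModelDefinitionError(
                    f"{self.name}: sparse projection not connected (call connect())"
                )
        return self.projection


@dataclass
class NNModel:
    """The complete declarative network description."""

    name: str
    dt: float = 1.0
    precision: str = "double"
    seed: int = 0
    neuron_populations: list[NeuronPopulation] = field(default_factory=list)
    synapse_populations: list[SynapsePopulation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.dt > 0:
            raise ModelDefinitionError(f"dt must be positive, got {self.dt}")
        if self.precision not in ("single", "double"):
            raise ModelDefinitionError(f"unknown precision {self.precision!r}")

    # -- lookups
    def neuron_population(self, name: str) -> NeuronPopulation:
        for p in self.neuron_populations:
            if p.name == name:
                return p
        raise KeyError(f"no neuron population named {name!r}")

    def synapse_population(self, name: str) -> SynapsePopulation:
        for p in self.synapse_populations:
            if p.name == name:
                return p
        raise KeyError(f"no synapse population named {name!r}")

    @property
    def total_neurons(self) -> int:
        return sum(p.n for p in self.neuron_populations)

    def global_id(self, pop_name: str, local_id: int) -> int:
        return self.neuron_population(pop_name).id_offset + local_id

    # -- registration
    def add_neuron_population(self, name, n, neuron_model, params, init_vars) -> NeuronPopulation:
        return add_neuron_population(self, name, n, neuron_model, params, init_vars)

    def add_synapse_population(self, *args, **kwargs) -> SynapsePopulation:
        return add_synapse_population(self, *args, **kwargs)

    def incoming(self, pop_name: str) -> list[SynapsePopulation]:
        return [s for s in self.synapse_populations if s.post.name == pop_name]

    def outgoing(self, pop_name: str) -> list[SynapsePopulation]:
        return [s for s in self.synapse_populations if s.pre.name == pop_name]


def add_neuron_population(
    model: NNModel, name: str, n: int, neuron_model: NeuronModel, params, init_vars
) -> NeuronPopulation:
    """Register a neuron population; global neuron ids are assigned
    contiguously in insertion order."""
    _check_fresh_name(model, name)
    if n < 1:
        raise ModelDefinitionError(f"population {name!r}: n must be >= 1, got {n}")
    _param_dict(neuron_model, params)  # length check, names in message
    init = _check_init_vars(f"population {name!r}", neuron_model, init_vars, n)
    pop = NeuronPopulation(name, int(n), neuron_model, list(params), init,
                           id_offset=model.total_neurons)
    model.neuron_populations.append(pop)
    return pop


def add_synapse_population(
    model: NNModel,
    name: str,
    pre: str | NeuronPopulation,
    post: str | NeuronPopulation,
    weight_model: WeightUpdateModel,
    connectivity_kind: str,
    conductance_mode: str,
    delay_steps: int,
    postsyn_model: PostSynapticModel,
    weight_params=(),
    weight_init_vars=(),
    postsyn_params=(),
    postsyn_init_vars=(),
) -> SynapsePopulation:
    """Register a synapse population between two existing neuron populations."""
    _check_fresh_name(model, name)
    pre_pop = model.neuron_population(pre if isinstance(pre, str) else pre.name)
    post_pop = model.neuron_population(post if isinstance(post, str) else post.name)
    if connectivity_kind not in ("dense", "sparse"):
        raise ModelDefinitionError(
            f"synapse population {name!r}: connectivity_kind must be dense|sparse"
        )
    if conductance_mode not in ("global", "individual"):
        raise ModelDefinitionError(
            f"synapse population {name!r}: conductance_mode must be global|individual"
        )
    if delay_steps < 0:
        raise ModelDefinitionError(f"synapse population {name!r}: delay_steps must be >= 0")
    _param_dict(weight_model, weight_params)
    _param_dict(postsyn_model, postsyn_params)
    winit = list(weight_init_vars)
    if len(winit) != len(weight_model.var_names):
        raise ModelDefinitionError(
            f"synapse population {name!r}: expected {len(weight_model.var_names)} initial "
            f"values for synapse variables {list(weight_model.var_names)}"
        )
    if conductance_mode == "global":
        for nm, v in zip(weight_model.var_names, winit):
            if np.ndim(v) != 0:
                raise ModelDefinitionError(
                    f"synapse population {name!r}: global conductance mode forbids "
                    f"per-synapse initialization arrays (variable {nm!r})"
                )
    pinit = _check_init_vars(f"synapse population {name!r}", postsyn_model,
                             postsyn_init_vars, post_pop.n)
    sp = SynapsePopulation(
        name, pre_pop, post_pop, weight_model, postsyn_model,
        connectivity_kind, conductance_mode, int(delay_steps),
        list(weight_params), winit, list(postsyn_params), pinit,
    )
    model.synapse_populations.append(sp)
    return sp


def _check_fresh_name(model: NNModel, name: str) -> None:
    taken = {p.name for p in model.neuron_populations}
    taken |= {p.name for p in model.synapse_populations}
    if name in taken:
        raise ModelDefinitionError(f"population name {name!r} already in use")


# ---------------------------------------------------------------- validation


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding, with population/model/snippet coordinates."""

    location: str  # e.g. "population Exc / model Izhikevich / sim_code"
    message: str

    def __str__(self):
        return f"{self.location}: {self.message}"


def validate_model(model: NNModel) -> list[Diagnostic]:
    """Check all structural invariants and snippet token resolution.

    Returns an empty list iff the model is well formed.  Never raises for
    model defects; findings are returned as diagnostics.  Idempotent and
    side-effect-free.
    """
    diags: list[Diagnostic] = []

    names: set[str] = set()
    for p in list(model.neuron_populations) + list(model.synapse_populations):
        if p.name in names:
            diags.append(Diagnostic(f"population {p.name!r}", "duplicate population name"))
        names.add(p.name)

    for pop in model.neuron_populations:
        loc = f"population {pop.name!r} / model {pop.model.name!r}"
        tmpl = pop.model
        if not tmpl.sim_code.strip():
            diags.append(Diagnostic(loc + " / sim_code", "sim_code is empty"))
        try:
            codegen.build_neuron_routines(pop, model.dt, model.precision)
        except (SnippetError, ModelDefinitionError) as e:
            diags.append(Diagnostic(loc, str(e)))

    for sp in model.synapse_populations:
        loc = f"synapse population {sp.name!r} / model {sp.weight_model.name!r}"
        wm = sp.weight_model
        if not (wm.sim_code.strip() or wm.sim_code_evnt.strip() or wm.synapse_dynamics.strip()):
            diags.append(Diagnostic(
                loc, "at least one of sim_code / sim_code_evnt / synapse_dynamics required"))
        if bool(wm.sim_code_evnt.strip()) != bool(wm.evnt_threshold.strip()):
            diags.append(Diagnostic(
                loc, "sim_code_evnt and evnt_threshold must be given together"))
        if {sp.pre.name, sp.post.name} - {p.name for p in model.neuron_populations}:
            diags.append(Diagnostic(loc, "references unregistered neuron population"))
        try:
            codegen.build_synapse_routines(sp, model.dt, model.precision)
        except (SnippetError, ModelDefinitionError) as e:
            diags.append(Diagnostic(loc, str(e)))
        try:
            codegen.build_postsyn_routines(sp, model.dt, model.precision)
        except (SnippetError, ModelDefinitionError) as e:
            diags.append(Diagnostic(
                f"synapse population {sp.name!r} / postsyn {sp.postsyn_model.name!r}", str(e)))

    return diags
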