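"""Scalar reference interpreter: the test oracle for the vectorized engine.

This module evaluates snippet ASTs by tree-walking with numpy double
scalars, walking neurons and synapses one at a time in explicit Python
loops, and replicates the engine's five phases with plain lists as delay
queues.  It shares only the snippet *parser* with the implementation (the
grammar has one definition); routine execution and the simulation loop are
written independently of the vectorized emitter and engine, so agreement
between the two is a meaningful check.

Conventions mirrored so double-precision trajectories match bitwise:

* statements execute one at a time over the whole population (so RNG call
  sites consume one full-width vector each, in statement order);
* the C conditional evaluates both branches and selects, like `np.where`;
* ``addtoinSyn`` contributions of one routine invocation are first summed
  per target (in ascending pre-id, then synapse-index order) and then added
  to ``inSyn``;
* locals start at 0.0; constants are Python floats.

Random draws are only supported in neuron sim code (where the engine's
built-ins put them).
"""

from __future__ import annotations

import numpy as np

from spikegen.codegen.parser import (
    Assign, Bin, BoolOp, Call, Cmp, Cond, If, Loop, Name, Not, Num, Ref,
    parse_expression, parse_statements,
)

_FUNCS = {
    "exp": np.exp, "log": np.log, "sin": np.sin, "cos": np.cos,
    "tanh": np.tanh, "sqrt": np.sqrt, "floor": np.floor, "abs": np.abs,
    "pow": np.power, "fmax": np.maximum, "fmin": np.minimum,
}


class ScalarContext:
    """Name resolution for one snippet evaluation.

    ``arrays`` maps a token name to (array, index_map) where index_map maps
    the element number of the current invocation to an array index (None
    means identity); ``consts`` maps names to floats; ``scalars`` to
    runtime scalars (t).
    """

    def __init__(self, n, arrays=None, consts=None, scalars=None, writable=()):
        self.n = n
        self.arrays = arrays or {}
        self.consts = consts or {}
        self.scalars = scalars or {}
        self.writable = set(writable)
        self.locals: dict[str, np.ndarray] = {}
        self.acc = None  # (partial array, post index map) for addtoinSyn

    def local(self, name):
        if name not in self.locals:
            self.locals[name] = np.zeros(self.n)
        return self.locals[name]


def _collect_draw_sites(node, sites):
    """In-order traversal collecting RNG call sites (matches the vectorized
    left-to-right evaluation order)."""
    if isinstance(node, Call):
        if node.fn in ("uniform", "normal"):
            sites.append(node)
        for a in node.args:
            _collect_draw_sites(a, sites)
    elif isinstance(node, (Bin, Cmp, BoolOp)):
        _collect_draw_sites(node.left, sites)
        _collect_draw_sites(node.right, sites)
    elif isinstance(node, Not):
        _collect_draw_sites(node.operand, sites)
    elif isinstance(node, Cond):
        for part in (node.test, node.then, node.other):
            _collect_draw_sites(part, sites)
    elif isinstance(node, Assign):
        _collect_draw_sites(node.value, sites)
    elif hasattr(node, "operand"):
        _collect_draw_sites(node.operand, sites)


class ScalarInterpreter:
    def __init__(self, ctx: ScalarContext, rng=None):
        self.ctx = ctx
        self.rng = rng
        self.draws: dict[int, np.ndarray] = {}

    # -- expression evaluation for element i
    def eval(self, node, i: int):
        ctx = self.ctx
        if isinstance(node, Num):
            return np.float64(float(node.text))
        if isinstance(node, Ref):
            return self._load(node.name, i)
        if isinstance(node, Name):
            nm = node.ident
            if nm in ctx.locals:
                return ctx.locals[nm][i]
            if nm in ("DT", "t") and (nm in ctx.consts or nm in ctx.scalars):
                return self._load(nm, i)
            return ctx.local(nm)[i]
        if isinstance(node, Call):
            if node.fn in ("uniform", "normal"):
                return self.draws[id(node)][i]
            return _FUNCS[node.fn](*(self.eval(a, i) for a in node.args))
        if isinstance(node, Bin):
            a, b = self.eval(node.left, i), self.eval(node.right, i)
            with np.errstate(all="ignore"):
                if node.op == "+":
                    return a + b
                if node.op == "-":
                    return a - b
                if node.op == "*":
                    return a * b
                if node.op == "/":
                    return a / b
                return a % b
        if isinstance(node, Cmp):
            a, b = self.eval(node.left, i), self.eval(node.right, i)
            return {"<": a < b, ">": a > b, "<=": a <= b, ">=": a >= b,
                    "==": a == b, "!=": a != b}[node.op]
        if isinstance(node, BoolOp):
            a, b = self.eval(node.left, i), self.eval(node.right, i)
            return np.logical_and(a, b) if node.op == "&&" else np.logical_or(a, b)
        if isinstance(node, Not):
            return np.logical_not(self.eval(node.operand, i))
        if isinstance(node, Cond):
            test = self.eval(node.test, i)
            then = self.eval(node.then, i)
            other = self.eval(node.other, i)
            return then if test else other
        if hasattr(node, "operand"):  # Unary minus
            return -self.eval(node.operand, i)
        raise AssertionError(f"unhandled node {node}")

    def _load(self, name, i):
        ctx = self.ctx
        if name in ctx.consts:
            return np.float64(ctx.consts[name])
        if name in ctx.scalars:
            return np.float64(ctx.scalars[name])
        arr, imap = ctx.arrays[name]
        return arr[i if imap is None else imap[i]]

    def _store(self, name, i, value):
        arr, imap = self.ctx.arrays[name]
        arr[i if imap is None else imap[i]] = value

    # -- statements
    def run(self, stmts, mask=None):
        for s in stmts:
            self.stmt(s, mask)

    def _predraw(self, stmt):
        sites: list = []
        _collect_draw_sites(stmt, sites)
        for site in sites:
            fn = "random" if site.fn == "uniform" else "standard_normal"
            self.draws[id(site)] = getattr(self.rng, fn)(self.ctx.n, dtype=np.float64)

    def stmt(self, node, mask):
        ctx = self.ctx
        if isinstance(node, Assign):
            self._predraw(node)
            if isinstance(node.target, Name) and node.target.ident == "addtoinSyn":
                partial, post_map = ctx.acc
                for i in range(ctx.n):
                    v = self.eval(node.value, i)
                    if mask is None or mask[i]:
                        partial[post_map[i]] += v
                return
            for i in range(ctx.n):
                with np.errstate(all="ignore"):
                    rhs = self.eval(node.value, i)
                    if isinstance(node.target, Name):
                        tgt = ctx.local(node.target.ident)
                        cur = tgt[i]
                        new = _apply_op(node.op, cur, rhs)
                        if mask is None or mask[i]:
                            tgt[i] = new
                    else:
                        cur = self._load(node.target.name, i)
                        new = _apply_op(node.op, cur, rhs)
                        if mask is None or mask[i]:
                            self._store(node.target.name, i, new)
        elif isinstance(node, If):
            self._predraw_expr(node.test)
            cond = np.array([bool(self.eval(node.test, i)) for i in range(ctx.n)])
            m1 = cond if mask is None else (mask & cond)
            self.run(node.then, m1)
            if node.orelse:
                m2 = ~cond if mask is None else (mask & ~cond)
                self.run(node.orelse, m2)
        elif isinstance(node, Loop):
            for _ in range(node.start, node.stop):
                self.run(node.body, mask)
        else:
            raise AssertionError(f"unhandled statement {node}")

    def _predraw_expr(self, expr):
        sites: list = []
        _collect_draw_sites(expr, sites)
        for site in sites:
            fn = "random" if site.fn == "uniform" else "standard_normal"
            self.draws[id(site)] = getattr(self.rng, fn)(self.ctx.n, dtype=np.float64)

    def eval_mask(self, expr):
        self._predraw_expr(expr)
        return np.array([bool(self.eval(expr, i)) for i in range(self.ctx.n)])


def _apply_op(op, cur, rhs):
    if op == "=":
        return rhs
    if op == "+=":
        return cur + rhs
    if op == "-=":
        return cur - rhs
    if op == "*=":
        return cur * rhs
    return cur / rhs


# ---------------------------------------------------------------- scalar engine


class ScalarSimulation:
    """Element-by-element re-implementation of the five-phase step loop.

    Only supports what the equivalence tests exercise: double precision,
    individual or global conductances, sparse or dense projections, delays,
    graded events, post-spike learning and synapse dynamics.
    """

    def __init__(self, model):
        self.model = model
        self.t = 0.0
        self.k = 0
        ss = np.random.SeedSequence(model.seed)
        children = ss.spawn(len(model.neuron_populations) + len(model.synapse_populations))
        self.pops = {}
        max_delay = {p.name: 0 for p in model.neuron_populations}
        for sp in model.synapse_populations:
            max_delay[sp.pre.name] = max(max_delay[sp.pre.name], sp.delay_steps)
        for i, pop in enumerate(model.neuron_populations):
            tmpl = pop.model
            self.pops[pop.name] = {
                "pop": pop,
                "vars": {nm: np.full(pop.n, v, dtype=float) if np.ndim(v) == 0
                         else np.asarray(v, dtype=float).copy()
                         for nm, v in zip(tmpl.var_names, pop.init_var_values)},
                "sT": np.full(pop.n, -1.0e10),
                "rng": np.random.default_rng(children[i]),
                "queue": [np.empty(0, dtype=int) for _ in range(max_delay[pop.name] + 1)],
                "qp": 0,
                "sim": parse_statements(tmpl.sim_code) if tmpl.sim_code.strip() else None,
                "thr": (parse_expression(tmpl.threshold_condition_code)
                        if tmpl.threshold_condition_code.strip() else None),
                "rst": parse_statements(tmpl.reset_code) if tmpl.reset_code.strip() else None,
                "params": pop.param_map(model.dt),
                "spikes": [],
            }
        self.projs = {}
        off = len(model.neuron_populations)
        for j, sp in enumerate(model.synapse_populations):
            proj = sp.built_projection()
            if proj.kind == "sparse":
                pairs = proj.pairs()
            else:
                pairs = proj.pairs()
            n_flat = (proj.n_conn if proj.kind == "sparse"
                      else proj.n_pre * proj.n_post)
            syn_vars = {}
            if sp.conductance_mode == "individual":
                for nm, init in zip(sp.weight_model.var_names, sp.weight_init_var_values):
                    if nm in sp.syn_var_arrays:
                        syn_vars[nm] = np.asarray(sp.syn_var_arrays[nm], dtype=float).copy()
                    elif np.ndim(init) == 0:
                        syn_vars[nm] = np.full(n_flat, init, dtype=float)
                    else:
                        syn_vars[nm] = np.asarray(init, dtype=float).reshape(-1).copy()
            wm = sp.weight_model
            self.projs[sp.name] = {
                "sp": sp, "proj": proj, "syn_vars": syn_vars,
                "inSyn": np.zeros(sp.post.n),
                "psm_vars": {nm: np.full(sp.post.n, v, dtype=float)
                             for nm, v in zip(sp.postsyn_model.var_names,
                                              sp.postsyn_init_var_values)},
                "wparams": sp.weight_param_map(model.dt),
                "pparams": sp.postsyn_param_map(model.dt),
                "sim": parse_statements(wm.sim_code) if wm.sim_code.strip() else None,
                "evnt": parse_statements(wm.sim_code_evnt) if wm.sim_code_evnt.strip() else None,
                "ethr": (parse_expression(wm.evnt_threshold)
                         if wm.evnt_threshold.strip() else None),
                "learn": (parse_statements(wm.sim_learn_post)
                          if wm.sim_learn_post.strip() else None),
                "dyn": (parse_statements(wm.synapse_dynamics)
                        if wm.synapse_dynamics.strip() else None),
                "apply": parse_statements(sp.postsyn_model.apply_input_code),
                "decay": (parse_statements(sp.postsyn_model.decay_code)
                          if sp.postsyn_model.decay_code.strip() else None),
                "equeue": ([np.empty(0, dtype=int) for _ in range(sp.delay_steps + 1)]
                           if wm.evnt_threshold.strip() else None),
                "eqp": 0,
            }

    # -- synapse gather in engine order: ascending pre id, then synapse index
    def _gather_rows(self, proj, pre_ids):
        syn, pre_of, post_of = [], [], []
        for i in pre_ids:
            if proj.kind == "sparse":
                sl = proj.row_slice(int(i))
                for s in range(sl.start, sl.stop):
                    syn.append(s)
                    pre_of.append(int(i))
                    post_of.append(int(proj.post_index[s]))
            else:
                for j in range(proj.n_post):
                    if proj.mask[int(i), j]:
                        syn.append(int(i) * proj.n_post + j)
                        pre_of.append(int(i))
                        post_of.append(j)
        return syn, pre_of, post_of

    def _gather_cols(self, proj, post_ids):
        syn, pre_of, post_of = [], [], []
        for j in post_ids:
            if proj.kind == "sparse":
                for i in range(proj.n_pre):
                    sl = proj.row_slice(i)
                    for s in range(sl.start, sl.stop):
                        if proj.post_index[s] == j:
                            syn.append(s)
                            pre_of.append(i)
                            post_of.append(int(j))
            else:
                for i in range(proj.n_pre):
                    if proj.mask[i, int(j)]:
                        syn.append(i * proj.n_post + int(j))
                        pre_of.append(i)
                        post_of.append(int(j))
        return syn, pre_of, post_of

    def _weight_ctx(self, pr, gather):
        syn, pre_of, post_of = gather
        sp = pr["sp"]
        pre_rt, post_rt = self.pops[sp.pre.name], self.pops[sp.post.name]
        n = len(syn)
        arrays = {}
        consts = dict(pr["wparams"])
        consts["DT"] = self.model.dt
        if sp.conductance_mode == "global":
            for nm, v in zip(sp.weight_model.var_names, sp.weight_init_var_values):
                consts[nm] = float(v)
        else:
            for nm, arr in pr["syn_vars"].items():
                arrays[nm] = (arr, syn)
        for nm, arr in pre_rt["vars"].items():
            arrays[f"{nm}_pre"] = (arr, pre_of)
        for nm, arr in post_rt["vars"].items():
            arrays.setdefault(f"{nm}_post", (arr, post_of))
        arrays["sT_pre"] = (pre_rt["sT"], pre_of)
        arrays["sT_post"] = (post_rt["sT"], post_of)
        arrays["inSyn"] = (pr["inSyn"].copy(), post_of)  # reads see pre-invocation values
        ctx = ScalarContext(n, arrays, consts, {"t": self.t})
        partial = np.zeros(sp.post.n)
        ctx.acc = (partial, post_of)
        return ctx, partial

    def _run_weight(self, pr, kind, gather):
        ctx, partial = self._weight_ctx(pr, gather)
        ScalarInterpreter(ctx).run(pr[kind])
        pr["inSyn"] += partial

    def step(self):
        model = self.model
        t = self.t
        # (1) synapse dynamics
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            if pr["dyn"] is not None:
                proj = pr["proj"]
                self._run_weight(pr, "dyn", self._gather_rows(proj, range(proj.n_pre)))
        # (2) neuron phase
        for pop in model.neuron_populations:
            rt = self.pops[pop.name]
            n = pop.n
            Isyn = np.zeros(n)
            for sp in model.synapse_populations:
                if sp.post.name != pop.name:
                    continue
                pr = self.projs[sp.name]
                arrays = {nm: (arr, None) for nm, arr in pr["psm_vars"].items()}
                for nm, arr in rt["vars"].items():
                    arrays.setdefault(nm, (arr, None))
                arrays["inSyn"] = (pr["inSyn"], None)
                arrays["Isyn"] = (Isyn, None)
                consts = dict(pr["pparams"])
                consts["DT"] = model.dt
                ctx = ScalarContext(n, arrays, consts, {"t": t})
                ScalarInterpreter(ctx).run(pr["apply"])
                if pr["decay"] is not None:
                    ctx2 = ScalarContext(n, arrays, consts, {"t": t})
                    ScalarInterpreter(ctx2).run(pr["decay"])
            arrays = {nm: (arr, None) for nm, arr in rt["vars"].items()}
            arrays["Isyn"] = (Isyn, None)
            arrays["sT"] = (rt["sT"], None)
            consts = dict(rt["params"])
            consts["DT"] = model.dt
            ctx = ScalarContext(n, arrays, consts, {"t": t})
            interp = ScalarInterpreter(ctx, rng=rt["rng"])
            if rt["sim"] is not None:
                interp.run(rt["sim"])
            ids = np.empty(0, dtype=int)
            if rt["thr"] is not None:
                mask = interp.eval_mask(rt["thr"])
                ids = np.flatnonzero(mask)
                if ids.size:
                    rt["sT"][ids] = t
                    if rt["rst"] is not None:
                        rarr = {nm: (arr, ids) for nm, arr in rt["vars"].items()}
                        rarr["Isyn"] = (Isyn, ids)
                        rarr["sT"] = (rt["sT"], ids)
                        rctx = ScalarContext(len(ids), rarr, consts, {"t": t})
                        ScalarInterpreter(rctx).run(rt["rst"])
            rt["queue"][rt["qp"]] = ids
            for sp in model.synapse_populations:
                if sp.pre.name != pop.name:
                    continue
                pr = self.projs[sp.name]
                if pr["ethr"] is not None:
                    earr = {f"{nm}_pre": (arr, None) for nm, arr in rt["vars"].items()}
                    earr["sT_pre"] = (rt["sT"], None)
                    consts_e = dict(pr["wparams"])
                    consts_e["DT"] = model.dt
                    if sp.conductance_mode == "global":
                        for nm, v in zip(sp.weight_model.var_names,
                                         sp.weight_init_var_values):
                            consts_e[nm] = float(v)
                    ectx = ScalarContext(n, earr, consts_e, {"t": t})
                    em = ScalarInterpreter(ectx).eval_mask(pr["ethr"])
                    pr["equeue"][pr["eqp"]] = np.flatnonzero(em)
            for i in ids:
                rt["spikes"].append((t, int(i)))
        # (3) spike/event transmission
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            d = sp.delay_steps
            pre_rt = self.pops[sp.pre.name]
            if pr["sim"] is not None:
                m = len(pre_rt["queue"])
                ids = pre_rt["queue"][(pre_rt["qp"] - d) % m]
                if len(ids):
                    self._run_weight(pr, "sim", self._gather_rows(pr["proj"], ids))
            if pr["evnt"] is not None:
                m = len(pr["equeue"])
                eids = pr["equeue"][(pr["eqp"] - d) % m]
                if len(eids):
                    self._run_weight(pr, "evnt", self._gather_rows(pr["proj"], eids))
        # (4) learning
        for sp in model.synapse_populations:
            pr = self.projs[sp.name]
            if pr["learn"] is not None:
                post_rt = self.pops[sp.post.name]
                pids = post_rt["queue"][post_rt["qp"]]
                if len(pids):
                    self._run_weight(pr, "learn", self._gather_cols(pr["proj"], pids))
        # (5) advance
        for rt in self.pops.values():
            rt["qp"] = (rt["qp"] + 1) % len(rt["queue"])
            rt["queue"][rt["qp"]] = np.empty(0, dtype=int)
        for pr in self.projs.values():
            if pr["equeue"] is not None:
                pr["eqp"] = (pr["eqp"] + 1) % len(pr["equeue"])
                pr["equeue"][pr["eqp"]] = np.empty(0, dtype=int)
        self.k += 1
        self.t = self.k * model.dt

    def run(self, steps):
        for _ in range(steps):
            self.step()
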