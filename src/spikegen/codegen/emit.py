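"""Synthesis of vectorized update routines from parsed snippets.

Each snippet is turned into the source text of a Python function operating on
whole numpy state arrays at once.  Branching (``if``/``?:``) is realised with
elementwise masks (`numpy.where`), so a statement inside a conditional takes
effect exactly for the elements whose condition holds; counted ``for`` loops
(sub-stepping) become ordinary Python loops around the vectorized body.

Accumulation into the post-synaptic activation (``addtoinSyn``) goes through
one deterministic helper: contributions of a single routine invocation are
summed per target in synapse order (ascending pre-synaptic id, then ascending
synapse index) into a scratch buffer in the model's precision, which is then
added to ``inSyn``.  This fixed serial order replaces the GPU's atomic,
schedule-dependent accumulation and is what makes runs bit-reproducible.

Random draws (``uniform()`` / ``normal()``) consume from the per-population
generator passed to the routine, one full-width vector per call site in
statement order, i.e. values land in neuron-id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .parser import (
    Assign,
    Bin,
    BoolOp,
    Call,
    Cmp,
    Cond,
    If,
    Loop,
    Name,
    Not,
    Num,
    Ref,
    SnippetError,
    Unary,
    parse_expression,
    parse_statements,
)

__all__ = [
    "Sym",
    "SymbolTable",
    "GeneratedRoutine",
    "substitute_tokens",
    "emit_routine",
]

#: functions callable from snippets -> numpy implementation
FUNCTIONS: dict[str, tuple[str, int]] = {
    "exp": ("_np.exp", 1),
    "log": ("_np.log", 1),
    "sin": ("_np.sin", 1),
    "cos": ("_np.cos", 1),
    "tanh": ("_np.tanh", 1),
    "sqrt": ("_np.sqrt", 1),
    "floor": ("_np.floor", 1),
    "abs": ("_np.abs", 1),
    "pow": ("_np.power", 2),
    "fmax": ("_np.maximum", 2),
    "fmin": ("_np.minimum", 2),
}
RANDOM_FUNCTIONS = {"uniform": "random", "normal": "standard_normal"}


@dataclass(frozen=True)
class Sym:
    """Resolution of one snippet token.

    kind:
      * ``const``  — numeric constant (parameter, derived parameter, DT)
      * ``array``  — full state array; ``load`` is the storage expression
      * ``scalar`` — runtime scalar such as the current time
    ``store`` is a format string with ``{v}`` for write-back (writable syms).
    """

    kind: str
    load: str = ""
    store: str | None = None
    value: float | None = None

    @property
    def storage(self) -> str:
        if self.kind == "const":
            return repr(float(self.value))
        return self.load


class SymbolTable(dict):
    """Mapping token name -> :class:`Sym`.

    Subscripting with a token name returns the storage *expression string*
    (constants render as their value), which is what token substitution
    splices into snippet text.  Plain-string values are accepted and wrapped.
    """

    def __init__(self, mapping: Mapping[str, "Sym | str"] | None = None):
        super().__init__()
        if mapping:
            for k, v in mapping.items():
                self.define(k, v)

    def define(self, name: str, sym: "Sym | str | float") -> None:
        if isinstance(sym, str):
            sym = Sym("array", load=sym)
        elif isinstance(sym, (int, float)):
            sym = Sym("const", value=float(sym))
        if name in self and self.sym(name).storage != sym.storage:
            raise SnippetError(f"symbol table already defines {name!r}")
        super().__setitem__(name, sym)

    def sym(self, name: str) -> Sym:
        return super().__getitem__(name)

    def __getitem__(self, name: str) -> str:
        return super().__getitem__(name).storage


def substitute_tokens(snippet: str, table: Mapping[str, str]) -> str:
    """Replace every ``$(name)`` in ``snippet`` by its storage expression.

    Text outside tokens is preserved byte for byte and the replacement is
    single-pass: substituted text is not rescanned for further tokens.
    Unresolved names and unbalanced ``$(`` constructs raise
    :class:`SnippetError` with the offending token / offset.
    """
    out: list[str] = []
    i, n = 0, len(snippet)
    while i < n:
        j = snippet.find("$", i)
        if j < 0:
            out.append(snippet[i:])
            break
        out.append(snippet[i:j])
        if j + 1 >= n or snippet[j + 1] != "(":
            raise SnippetError(f"malformed token at offset {j}: '$' not followed by '('")
        k = snippet.find(")", j + 2)
        if k < 0:
            raise SnippetError(f"malformed token at offset {j}: unbalanced parenthesis in $()")
        name = snippet[j + 2: k]
        if not name.isidentifier():
            raise SnippetError(f"malformed token at offset {j}: invalid $() name {name!r}")
        try:
            out.append(table[name])
        except KeyError:
            raise SnippetError(f"unresolved token $({name})") from None
        i = k + 1
    return "".join(out)


@dataclass
class GeneratedRoutine:
    """A synthesized update routine: source text plus its compiled entry."""

    source_text: str
    entry: Callable
    provenance: tuple[str, str]  # (population/projection, snippet kind)


# ---------------------------------------------------------------- emitter


class _Emitter:
    def __init__(
        self,
        symbols: SymbolTable,
        kind: str,
        *,
        acc_index: str | None = None,
        acc_target: str = "inSyn",
    ):
        self.symbols = symbols
        self.kind = kind
        self.acc_index = acc_index
        self.acc_target = acc_target
        self.lines: list[tuple[int, str]] = []
        self.used: set[str] = set()
        self.assigned: set[str] = set()
        self.locals: set[str] = set()
        self.loop_vars: list[str] = []
        self._mask = 0  # counters for fresh temporaries
        self._tmp = 0

    # -- helpers
    def err(self, msg: str) -> SnippetError:
        return SnippetError(f"{msg} (in {self.kind} code)")

    def emit(self, indent: int, line: str) -> None:
        self.lines.append((indent, line))

    def collect_locals(self, stmts: Iterable) -> None:
        for s in stmts:
            if isinstance(s, Assign) and isinstance(s.target, Name):
                name = s.target.ident
                if name not in self.symbols and name != "addtoinSyn":
                    self.locals.add(name)
            elif isinstance(s, If):
                self.collect_locals(s.then)
                self.collect_locals(s.orelse)
            elif isinstance(s, Loop):
                self.collect_locals(s.body)

    # -- expressions
    def expr(self, node) -> str:
        if isinstance(node, Num):
            text = node.text
            return text if ("." in text or "e" in text or "E" in text) else f"{text}.0"
        if isinstance(node, Ref):
            return self.resolve(node.name, token=True)
        if isinstance(node, Name):
            ident = node.ident
            if ident in self.loop_vars:
                return f"l_{ident}"
            if ident in self.locals:
                return f"l_{ident}"
            if ident in ("DT", "t") and ident in self.symbols:
                return self.resolve(ident, token=False)
            if ident in self.symbols:
                raise self.err(f"symbol {ident!r} must be written as $({ident})")
            raise self.err(f"unknown identifier {ident!r}")
        if isinstance(node, Call):
            return self.call(node)
        if isinstance(node, Unary):
            return f"(-({self.expr(node.operand)}))"
        if isinstance(node, Bin):
            return f"(({self.expr(node.left)}) {node.op} ({self.expr(node.right)}))"
        if isinstance(node, Cmp):
            return f"(({self.expr(node.left)}) {node.op} ({self.expr(node.right)}))"
        if isinstance(node, BoolOp):
            fn = "_np.logical_and" if node.op == "&&" else "_np.logical_or"
            return f"{fn}({self.expr(node.left)}, {self.expr(node.right)})"
        if isinstance(node, Not):
            return f"_np.logical_not({self.expr(node.operand)})"
        if isinstance(node, Cond):
            return (
                f"_np.where({self.expr(node.test)}, "
                f"{self.expr(node.then)}, {self.expr(node.other)})"
            )
        raise self.err(f"cannot emit expression node {node!r}")

    def resolve(self, name: str, token: bool) -> str:
        try:
            sym = self.symbols.sym(name)
        except KeyError:
            raise self.err(f"unresolved token $({name})") from None
        if sym.kind == "const":
            return f"({float(sym.value)!r})"
        if sym.kind == "scalar":
            return sym.load
        self.used.add(name)
        return f"v_{name}"

    def call(self, node: Call) -> str:
        if node.fn in RANDOM_FUNCTIONS:
            if node.args:
                raise self.err(f"{node.fn}() takes no arguments")
            return f"_rng.{RANDOM_FUNCTIONS[node.fn]}(_n, dtype=_fdt)"
        if node.fn not in FUNCTIONS:
            raise self.err(f"function {node.fn!r} is not in the snippet whitelist")
        impl, arity = FUNCTIONS[node.fn]
        if len(node.args) != arity:
            raise self.err(f"{node.fn}() expects {arity} argument(s)")
        return f"{impl}({', '.join(self.expr(a) for a in node.args)})"

    # -- statements
    def statements(self, stmts: Iterable, indent: int, mask: str | None) -> None:
        for s in stmts:
            self.statement(s, indent, mask)

    def statement(self, node, indent: int, mask: str | None) -> None:
        if isinstance(node, Assign):
            self.assign(node, indent, mask)
        elif isinstance(node, If):
            test = self.expr(node.test)
            self._mask += 1
            mv = f"_m{self._mask}"
            if mask is None:
                self.emit(indent, f"{mv} = _np.asarray({test}, dtype=bool)")
            else:
                self.emit(indent, f"{mv} = _np.logical_and({mask}, {test})")
            self.statements(node.then, indent, mv)
            if node.orelse:
                self._mask += 1
                me = f"_m{self._mask}"
                if mask is None:
                    self.emit(indent, f"{me} = _np.logical_not({mv})")
                else:
                    self.emit(indent, f"{me} = _np.logical_and({mask}, _np.logical_not({mv}))")
                self.statements(node.orelse, indent, me)
        elif isinstance(node, Loop):
            self.loop_vars.append(node.var)
            self.emit(indent, f"for l_{node.var} in range({node.start}, {node.stop}):")
            self.statements(node.body, indent + 1, mask)
            self.loop_vars.pop()
            if not node.body:
                self.emit(indent + 1, "pass")
        else:
            raise self.err(f"cannot emit statement node {node!r}")

    def assign(self, node: Assign, indent: int, mask: str | None) -> None:
        rhs = self.expr(node.value)
        # the addtoinSyn primitive: accumulate into the target's activation
        if isinstance(node.target, Name) and node.target.ident == "addtoinSyn":
            if self.acc_index is None:
                raise self.err("addtoinSyn is only available in synaptic update code")
            if node.op != "=":
                raise self.err("addtoinSyn only supports plain assignment")
            self._tmp += 1
            tv = f"_c{self._tmp}"
            if mask is None:
                self.emit(indent, f"{tv} = {rhs}")
            else:
                self.emit(indent, f"{tv} = _np.where({mask}, {rhs}, 0.0)")
            self.emit(indent, f"_accumulate({self.acc_target}, {self.acc_index}, {tv}, _fdt)")
            return
        if isinstance(node.target, Name):
            name = node.target.ident
            if name in self.loop_vars:
                raise self.err(f"cannot assign to loop variable {name!r}")
            if name in self.symbols:
                raise self.err(f"symbol {name!r} must be written as $({name})")
            lhs = f"l_{name}"
        else:
            name = node.target.name
            try:
                sym = self.symbols.sym(name)
            except KeyError:
                raise self.err(f"unresolved token $({name})") from None
            if sym.kind == "const":
                raise self.err(f"$({name}) is a constant and cannot be assigned")
            if sym.store is None:
                raise self.err(f"$({name}) is read-only in {self.kind} code")
            self.used.add(name)
            self.assigned.add(name)
            lhs = f"v_{name}"
        value = rhs if node.op == "=" else f"({lhs} {node.op[0]} ({rhs}))"
        if mask is None:
            self.emit(indent, f"{lhs} = {value}")
        else:
            self.emit(indent, f"{lhs} = _np.where({mask}, {value}, {lhs})")


def emit_routine(
    snippet: str,
    symbols: SymbolTable,
    kind: str,
    provenance: str,
    *,
    args: str,
    n_expr: str,
    expression: bool = False,
    acc_index: str | None = None,
    acc_target: str = "inSyn",
    extra_env: Mapping[str, object] | None = None,
    dtype=np.float64,
) -> GeneratedRoutine:
    """Synthesize one routine from ``snippet`` under ``symbols``.

    ``expression=True`` builds a boolean-mask routine (threshold conditions);
    otherwise the snippet is a statement block mutating its state arrays in
    place.  ``args`` is the literal argument list of the generated function
    and ``n_expr`` the expression for the element count (used for masks and
    RNG draws).
    """
    em = _Emitter(symbols, kind, acc_index=acc_index, acc_target=acc_target)
    if expression:
        node = parse_expression(snippet)
        result = em.expr(node)
        body: list[tuple[int, str]] = em.lines + [(0, f"return _bool_mask({result}, _n)")]
    else:
        stmts = parse_statements(snippet)
        em.collect_locals(stmts)
        em.statements(stmts, 0, None)
        body = em.lines

    lines = [f"def _routine({args}):", f"    _n = {n_expr}"]
    for name in sorted(em.used):
        lines.append(f"    v_{name} = {symbols.sym(name).load}")
    if not expression and em.locals:
        for name in sorted(em.locals):
            lines.append(f"    l_{name} = 0.0")
    lines.append("    with _np.errstate(all='ignore'):")
    if not body:
        body = [(0, "pass")]
    for ind, text in body:
        lines.append("        " + "    " * ind + text)
    for name in sorted(em.assigned):
        sym = symbols.sym(name)
        lines.append("    " + sym.store.format(v=f"v_{name}"))
    source = "\n".join(lines) + "\n"

    env: dict[str, object] = {
        "_np": np,
        "_fdt": dtype,
        "_accumulate": _accumulate,
        "_bool_mask": _bool_mask,
        "_wb": _writeback,
    }
    if extra_env:
        env.update(extra_env)
    code = compile(source, f"<spikegen {provenance}:{kind}>", "exec")
    exec(code, env)
    return GeneratedRoutine(source, env["_routine"], (provenance, kind))


# ---------------------------------------------------------------- runtime helpers


def _accumulate(acc: np.ndarray, idx: np.ndarray, vals, dtype) -> None:
    """Deterministically add per-synapse contributions to their targets.

    Contributions are summed per target in synapse order into a zeroed
    scratch buffer of the accumulator's precision, then added to ``acc`` —
    the same convention in both precisions and for dense and sparse storage.
    """
    vals = np.broadcast_to(np.asarray(vals), idx.shape)
    if acc.dtype == np.float64:
        part = np.bincount(idx, weights=vals, minlength=acc.size)
    else:
        part = np.zeros_like(acc)
        np.add.at(part, idx, vals.astype(acc.dtype, copy=False))
    acc += part


def _writeback(value, old: np.ndarray) -> np.ndarray:
    """Materialise an assigned state array in the old array's shape/dtype.

    Always copies, so write-backs cannot corrupt other locals that still
    alias the previous buffer (e.g. a previous-voltage variable assigned
    from the voltage itself).
    """
    return np.asarray(np.broadcast_to(value, old.shape), dtype=old.dtype).copy()


def _bool_mask(x, n: int) -> np.ndarray:
    a = np.asarray(x)
    if a.shape == ():
        return np.full(n, bool(a))
    return a.astype(bool, copy=False)
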