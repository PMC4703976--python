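"""Parser for the snippet mini-language.

Snippets are C-like one-liners (or short statement blocks) describing one
time-step's worth of state updates.  The accepted grammar is a restricted
statement/expression subset:

* statements: assignment (``=``, ``+=``, ``-=``, ``*=``, ``/=``) terminated by
  ``;``, ``if (...) {...} else {...}``, and counted ``for`` loops of the form
  ``for (j = 0; j < 5; j++) { ... }`` used for sub-stepping;
* expressions: arithmetic (``+ - * / %``), comparisons, logical ``&& || !``,
  the C conditional ``cond ? a : b``, parentheses, numeric literals, and calls
  to a whitelist of functions (``exp log sin cos tanh pow sqrt fmax fmin
  floor abs`` plus the RNG primitives ``uniform()`` / ``normal()``);
* model quantities are referenced as ``$(name)`` tokens; the predefined
  symbols ``DT`` and ``t`` may also appear bare, as may snippet-local
  temporaries introduced by assignment.

Type keywords (``scalar``, ``float``, ``double``, ``int``) before a local
declaration are accepted and ignored.  The Unicode minus sign is normalised
to ASCII ``-`` before scanning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class SnippetError(ValueError):
    """Malformed snippet text or an unresolvable reference within it."""


# ---------------------------------------------------------------- AST

@dataclass(frozen=True)
class Num:
    text: str


@dataclass(frozen=True)
class Name:
    ident: str


@dataclass(frozen=True)
class Ref:
    """A ``$(name)`` token."""

    name: str


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple


@dataclass(frozen=True)
class Unary:
    op: str
    operand: object


@dataclass(frozen=True)
class Bin:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class Cmp:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class BoolOp:
    op: str  # '&&' | '||'
    left: object
    right: object


@dataclass(frozen=True)
class Not:
    operand: object


@dataclass(frozen=True)
class Cond:
    test: object
    then: object
    other: object


@dataclass(frozen=True)
class Assign:
    target: object  # Ref or Name
    op: str  # '=', '+=', '-=', '*=', '/='
    value: object


@dataclass(frozen=True)
class If:
    test: object
    then: tuple
    orelse: tuple


@dataclass(frozen=True)
class Loop:
    var: str
    start: int
    stop: int
    body: tuple


# ---------------------------------------------------------------- scanner

_TWO_CHAR = ("==", "!=", "<=", ">=", "&&", "||", "+=", "-=", "*=", "/=", "++")
_ONE_CHAR = "+-*/%<>=!?:;,(){}"
_NUM_RE = re.compile(r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z_0-9]*")
_TYPE_KEYWORDS = {"scalar", "float", "double", "int", "unsigned", "long"}


@dataclass
class _Tok:
    kind: str  # 'num' | 'ident' | 'ref' | 'op' | 'eof'
    text: str
    pos: int


def _normalise(text: str) -> str:
    return text.replace("−", "-").replace(" ", " ")


def tokenize(text: str) -> list[_Tok]:
    text = _normalise(text)
    toks: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if text.startswith("//", i):
            j = text.find("\n", i)
            i = n if j < 0 else j + 1
            continue
        if c == "$":
            if i + 1 >= n or text[i + 1] != "(":
                raise SnippetError(f"malformed token at offset {i}: '$' not followed by '('")
            m = _IDENT_RE.match(text, i + 2)
            if m is None:
                raise SnippetError(f"malformed token at offset {i}: empty or invalid $() name")
            j = m.end()
            if j >= n or text[j] != ")":
                raise SnippetError(f"malformed token at offset {i}: unbalanced parenthesis in $()")
            toks.append(_Tok("ref", m.group(), i))
            i = j + 1
            continue
        m = _NUM_RE.match(text, i)
        if m and c.isdigit() or (c == "." and m):
            toks.append(_Tok("num", m.group(), i))
            i = m.end()
            continue
        m = _IDENT_RE.match(text, i)
        if m:
            toks.append(_Tok("ident", m.group(), i))
            i = m.end()
            continue
        two = text[i: i + 2]
        if two in _TWO_CHAR:
            toks.append(_Tok("op", two, i))
            i += 2
            continue
        if c in _ONE_CHAR:
            toks.append(_Tok("op", c, i))
            i += 1
            continue
        raise SnippetError(f"unexpected character {c!r} at offset {i}")
    toks.append(_Tok("eof", "", n))
    return toks


# ---------------------------------------------------------------- parser

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = tokenize(text)
        self.i = 0

    # -- token helpers
    def peek(self) -> _Tok:
        return self.toks[self.i]

    def next(self) -> _Tok:
        t = self.toks[self.i]
        self.i += 1
        return t

    def accept(self, kind: str, text: str | None = None):
        t = self.peek()
        if t.kind == kind and (text is None or t.text == text):
            return self.next()
        return None

    def expect(self, kind: str, text: str | None = None) -> _Tok:
        t = self.accept(kind, text)
        if t is None:
            got = self.peek()
            want = text or kind
            raise SnippetError(
                f"expected {want!r} at offset {got.pos}, found {got.text or 'end of snippet'!r}"
            )
        return t

    # -- statements
    def program(self) -> tuple:
        stmts = []
        while self.peek().kind != "eof":
            stmts.append(self.statement())
        return tuple(stmts)

    def statement(self):
        t = self.peek()
        if t.kind == "ident" and t.text == "if":
            return self.if_statement()
        if t.kind == "ident" and t.text == "for":
            return self.for_statement()
        if t.kind == "ident" and t.text in _TYPE_KEYWORDS:
            self.next()  # local declaration type keyword; ignored
        return self.simple_statement()

    def if_statement(self) -> If:
        self.expect("ident", "if")
        self.expect("op", "(")
        test = self.expression()
        self.expect("op", ")")
        then = self.block_or_single()
        orelse: tuple = ()
        if self.accept("ident", "else"):
            if self.peek().kind == "ident" and self.peek().text == "if":
                orelse = (self.if_statement(),)
            else:
                orelse = self.block_or_single()
        return If(test, then, orelse)

    def for_statement(self) -> Loop:
        self.expect("ident", "for")
        self.expect("op", "(")
        if self.peek().kind == "ident" and self.peek().text in _TYPE_KEYWORDS:
            self.next()
        var = self.expect("ident").text
        self.expect("op", "=")
        start = self.expect("num").text
        self.expect("op", ";")
        v2 = self.expect("ident").text
        if v2 != var:
            raise SnippetError(f"loop condition must test loop variable {var!r}")
        self.expect("op", "<")
        stop = self.expect("num").text
        self.expect("op", ";")
        v3 = self.expect("ident").text
        if v3 != var:
            raise SnippetError(f"loop update must increment loop variable {var!r}")
        self.expect("op", "++")
        self.expect("op", ")")
        body = self.block_or_single()
        try:
            a, b = int(start), int(stop)
        except ValueError as e:
            raise SnippetError("loop bounds must be integer literals") from e
        return Loop(var, a, b, body)

    def block_or_single(self) -> tuple:
        if self.accept("op", "{"):
            stmts = []
            while not self.accept("op", "}"):
                if self.peek().kind == "eof":
                    raise SnippetError("unterminated '{' block")
                stmts.append(self.statement())
            return tuple(stmts)
        return (self.statement(),)

    def simple_statement(self) -> Assign:
        t = self.peek()
        if t.kind == "ref":
            target = Ref(self.next().text)
        elif t.kind == "ident":
            target = Name(self.next().text)
        else:
            raise SnippetError(f"expected statement at offset {t.pos}, found {t.text!r}")
        op = self.peek()
        if op.kind == "op" and op.text in ("=", "+=", "-=", "*=", "/="):
            self.next()
        else:
            raise SnippetError(f"expected assignment operator at offset {op.pos}")
        value = self.expression()
        self.expect("op", ";")
        return Assign(target, op.text, value)

    # -- expressions (precedence climbing)
    def expression(self):
        return self.ternary()

    def ternary(self):
        test = self.logic_or()
        if self.accept("op", "?"):
            then = self.expression()
            self.expect("op", ":")
            other = self.ternary()
            return Cond(test, then, other)
        return test

    def logic_or(self):
        node = self.logic_and()
        while self.accept("op", "||"):
            node = BoolOp("||", node, self.logic_and())
        return node

    def logic_and(self):
        node = self.logic_not()
        while self.accept("op", "&&"):
            node = BoolOp("&&", node, self.logic_not())
        return node

    def logic_not(self):
        if self.accept("op", "!"):
            return Not(self.logic_not())
        return self.comparison()

    def comparison(self):
        node = self.additive()
        t = self.peek()
        if t.kind == "op" and t.text in ("<", ">", "<=", ">=", "==", "!="):
            self.next()
            return Cmp(t.text, node, self.additive())
        return node

    def additive(self):
        node = self.multiplicative()
        while True:
            t = self.peek()
            if t.kind == "op" and t.text in ("+", "-"):
                self.next()
                node = Bin(t.text, node, self.multiplicative())
            else:
                return node

    def multiplicative(self):
        node = self.unary()
        while True:
            t = self.peek()
            if t.kind == "op" and t.text in ("*", "/", "%"):
                self.next()
                node = Bin(t.text, node, self.unary())
            else:
                return node

    def unary(self):
        if self.accept("op", "-"):
            return Unary("-", self.unary())
        if self.accept("op", "+"):
            return self.unary()
        return self.primary()

    def primary(self):
        t = self.next()
        if t.kind == "num":
            return Num(t.text)
        if t.kind == "ref":
            return Ref(t.text)
        if t.kind == "ident":
            if self.accept("op", "("):
                args = []
                if not self.accept("op", ")"):
                    args.append(self.expression())
                    while self.accept("op", ","):
                        args.append(self.expression())
                    self.expect("op", ")")
                return Call(t.text, tuple(args))
            return Name(t.text)
        if t.kind == "op" and t.text == "(":
            node = self.expression()
            self.expect("op", ")")
            return node
        raise SnippetError(f"unexpected {t.text or 'end of snippet'!r} at offset {t.pos}")


def parse_statements(text: str) -> tuple:
    """Parse a statement snippet (sim/reset/decay/weight-update code)."""
    return _Parser(text).program()


def parse_expression(text: str):
    """Parse a boolean/value expression snippet (threshold conditions)."""
    p = _Parser(text)
    node = p.expression()
    p.accept("op", ";")
    p.expect("eof")
    return node


def referenced_tokens(text: str) -> set[str]:
    """Names of all ``$()`` tokens appearing in the snippet."""
    return {t.text for t in tokenize(text) if t.kind == "ref"}
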