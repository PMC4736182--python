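"""The DNA part scripting language: parser and evaluator.

Scripts declare named DNA parts and compose them into target sequences:

    # quoted strings are DNA literals (case-insensitive, ACGT only)
    prom  = "TTGACAATTAATCATCCGGCTCG"
    gene  = prom + "ATGAGCAAAGGAGAAGAAC"
    cds   = gene[24-42]            # 1-based, inclusive at both ends
    gene([1-6] = "TTTACA")         # mutate a span in place
    targets = gene, cds

Statements execute in declaration order with purely functional
semantics: mutating a part rebinds its name from that line onward; parts
already derived from the old value keep it. A part name must be defined
before use, so reference cycles cannot be written. The ``targets``
statement lists the sequences an assembly protocol should produce; it
accepts part names, quoted literals, or any part expression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

from .sequence import ALPHABET, clean

__all__ = [
    "ParseError",
    "EvalError",
    "Literal",
    "Ref",
    "Concat",
    "Slice",
    "Mutate",
    "Script",
    "parse_script",
    "evaluate",
    "to_source",
]


class ParseError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"line {line}, column {col}: {message}")
        self.line = line
        self.col = col


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------- expressions


@dataclass(frozen=True)
class Literal:
    text: str


@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class Concat:
    left: "PartExpr"
    right: "PartExpr"


@dataclass(frozen=True)
class Slice:
    part: "PartExpr"
    start: int
    end: int


@dataclass(frozen=True)
class Mutate:
    part: "PartExpr"
    start: int
    end: int
    replacement: "PartExpr"


PartExpr = Union[Literal, Ref, Concat, Slice, Mutate]


@dataclass
class Script:
    statements: list[tuple[str, PartExpr]] = field(default_factory=list)
    targets: list[tuple[str, PartExpr]] = field(default_factory=list)


# ----------------------------------------------------------------- tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<STRING>"[^"]*"|'[^']*')
  | (?P<NUMBER>\d+)
  | (?P<IDENT>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<OP>[=+\-(),\[\]])
  | (?P<WS>\s+)
  | (?P<BAD>.)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Token:
    kind: str
    value: str
    line: int
    col: int


def _tokenize(line: str, lineno: int) -> list[_Token]:
    out = []
    for m in _TOKEN_RE.finditer(line):
        kind = m.lastgroup
        if kind == "WS":
            continue
        if kind == "BAD":
            raise ParseError(f"unexpected character {m.group()!r}", lineno, m.start() + 1)
        out.append(_Token(kind, m.group(), lineno, m.start() + 1))
    return out


class _Parser:
    def __init__(self, tokens: list[_Token], lineno: int, defined: set[str]):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno
        self.defined = defined

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else None
            col = (last.col + len(last.value)) if last else 1
            raise ParseError("unexpected end of line", self.lineno, col)
        self.pos += 1
        return tok

    def expect(self, value: str) -> _Token:
        tok = self.next()
        if tok.value != value:
            raise ParseError(f"expected {value!r}, found {tok.value!r}", tok.line, tok.col)
        return tok

    # expr := term ('+' term)*
    def expr(self) -> PartExpr:
        node = self.term()
        while (tok := self.peek()) is not None and tok.value == "+":
            self.next()
            node = Concat(node, self.term())
        return node

    # term := primary ('[' NUMBER '-' NUMBER ']')*
    def term(self) -> PartExpr:
        node = self.primary()
        while (tok := self.peek()) is not None and tok.value == "[":
            self.next()
            start, end = self.index_pair()
            self.expect("]")
            node = Slice(node, start, end)
        return node

    def index_pair(self) -> tuple[int, int]:
        stok = self.next()
        if stok.kind != "NUMBER":
            raise ParseError(f"expected index, found {stok.value!r}", stok.line, stok.col)
        self.expect("-")
        etok = self.next()
        if etok.kind != "NUMBER":
            raise ParseError(f"expected index, found {etok.value!r}", etok.line, etok.col)
        start, end = int(stok.value), int(etok.value)
        if not (1 <= start <= end):
            raise ParseError(
                f"invalid index range {start}-{end} (1-based, start <= end)",
                stok.line,
                stok.col,
            )
        return start, end

    def primary(self) -> PartExpr:
        tok = self.next()
        if tok.kind == "STRING":
            body = tok.value[1:-1]
            bad = set(body.upper()) - ALPHABET
            if bad:
                raise ParseError(
                    f"non-ACGT characters {sorted(bad)!r} in DNA literal", tok.line, tok.col
                )
            if not body:
                raise ParseError("empty DNA literal", tok.line, tok.col)
            return Literal(body.upper())
        if tok.kind == "IDENT":
            if tok.value not in self.defined:
                raise ParseError(f"undefined part {tok.value!r}", tok.line, tok.col)
            return Ref(tok.value)
        if tok.value == "(":
            node = self.expr()
            self.expect(")")
            return node
        raise ParseError(f"unexpected token {tok.value!r}", tok.line, tok.col)

    def at_end(self) -> bool:
        return self.pos >= len(self.tokens)


# -------------------------------------------------------------------- parser


def parse_script(source: str) -> Script:
    """Parse DSL text into a :class:`Script`; errors carry line and column."""
    script = Script()
    defined: set[str] = set()
    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = _tokenize(line, lineno)
        head = tokens[0]
        if head.kind != "IDENT":
            raise ParseError(f"statement must start with a name", head.line, head.col)
        if head.value == "targets":
            p = _Parser(tokens[1:], lineno, defined)
            p.expect("=")
            entries = [p.expr()]
            while not p.at_end():
                p.expect(",")
                entries.append(p.expr())
            for e in entries:
                label = e.name if isinstance(e, Ref) else f"target_{len(script.targets) + 1}"
                script.targets.append((label, e))
            continue
        if len(tokens) >= 2 and tokens[1].value == "(":
            # mutation statement: Name([s-e] = expr)
            p = _Parser(tokens[1:], lineno, defined)
            p.expect("(")
            p.expect("[")
            start, end = p.index_pair()
            p.expect("]")
            p.expect("=")
            repl = p.expr()
            p.expect(")")
            if not p.at_end():
                t = p.next()
                raise ParseError(f"trailing input {t.value!r}", t.line, t.col)
            if head.value not in defined:
                raise ParseError(f"undefined part {head.value!r}", head.line, head.col)
            script.statements.append(
                (head.value, Mutate(Ref(head.value), start, end, repl))
            )
            continue
        p = _Parser(tokens[1:], lineno, defined)
        p.expect("=")
        expr = p.expr()
        if not p.at_end():
            t = p.next()
            raise ParseError(f"trailing input {t.value!r}", t.line, t.col)
        script.statements.append((head.value, expr))
        defined.add(head.value)
    return script


# ----------------------------------------------------------------- evaluator


def _eval(expr: PartExpr, env: dict[str, str]) -> str:
    if isinstance(expr, Literal):
        return expr.text
    if isinstance(expr, Ref):
        try:
            return env[expr.name]
        except KeyError:
            raise EvalError(f"undefined part {expr.name!r}") from None
    if isinstance(expr, Concat):
        return _eval(expr.left, env) + _eval(expr.right, env)
    if isinstance(expr, Slice):
        value = _eval(expr.part, env)
        if not (1 <= expr.start <= expr.end <= len(value)):
            raise EvalError(
                f"slice {expr.start}-{expr.end} out of range for part of length {len(value)}"
            )
        return value[expr.start - 1 : expr.end]
    if isinstance(expr, Mutate):
        value = _eval(expr.part, env)
        if not (1 <= expr.start <= expr.end <= len(value)):
            raise EvalError(
                f"mutation {expr.start}-{expr.end} out of range for part of length {len(value)}"
            )
        repl = _eval(expr.replacement, env)
        out = value[: expr.start - 1] + repl + value[expr.end :]
        if not out:
            raise EvalError("mutation produced an empty part")
        return out
    raise TypeError(f"unknown expression node {expr!r}")


def evaluate(script: Script) -> list[tuple[str, str]]:
    """Resolve every target to a concrete sequence, in declaration order.

    Returns ordered ``(target id, sequence)`` pairs. Statement order is
    the program order; rebinding a name affects only later statements.
    """
    env: dict[str, str] = {}
    for name, expr in script.statements:
        env[name] = clean(_eval(expr, env), context=name)
    if not script.targets:
        raise EvalError("script declares no targets")
    out = []
    for label, expr in script.targets:
        seq = clean(_eval(expr, env), context=label)
        if not seq:
            raise EvalError(f"target {label} resolved to an empty sequence")
        out.append((label, seq))
    return out


# ------------------------------------------------------------------- printer


def _print_expr(expr: PartExpr) -> str:
    if isinstance(expr, Literal):
        return f'"{expr.text}"'
    if isinstance(expr, Ref):
        return expr.name
    if isinstance(expr, Concat):
        return f"{_print_expr(expr.left)} + {_print_expr(expr.right)}"
    if isinstance(expr, Slice):
        inner = _print_expr(expr.part)
        if isinstance(expr.part, Concat):
            inner = f"({inner})"
        return f"{inner}[{expr.start}-{expr.end}]"
    if isinstance(expr, Mutate):
        raise TypeError("mutations print as statements, not expressions")
    raise TypeError(f"unknown expression node {expr!r}")


def to_source(script: Script) -> str:
    """Canonical printer; ``parse_script(to_source(s))`` evaluates identically."""
    lines = []
    for name, expr in script.statements:
        if isinstance(expr, Mutate) and isinstance(expr.part, Ref) and expr.part.name == name:
            lines.append(
                f"{name}([{expr.start}-{expr.end}] = {_print_expr(expr.replacement)})"
            )
        else:
            lines.append(f"{name} = {_print_expr(expr)}")
    if script.targets:
        lines.append(
            "targets = " + ", ".join(_print_expr(e) for _, e in script.targets)
        )
    return "\n".join(lines) + "\n"
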