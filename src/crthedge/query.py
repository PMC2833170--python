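"""Abstract syntax and parser for the numbered-line Ovid-style query dialect.

A strategy is a sequence of numbered lines, each either

* a term expression scoped to a field — ``cluster$ adj2 randomi$.tw.``,
  ``randomized controlled trial.pt.`` — built from truncated terms
  (``$`` = unlimited truncation, ``?`` = at most one extra character),
  phrases (adjacent words), the proximity operator ``adjN`` and the
  Boolean operators;
* a MeSH heading line — ``cluster analysis/``;
* a Boolean combination of earlier line numbers — ``2 NOT (2 AND 3)``.

Operator precedence is OR < AND < NOT < adjN, all left-associative; NOT is
binary (``a NOT b`` keeps a's hits that are not b's).  A trailing field
suffix binds to the largest preceding pure term-level expression, so
``cluster$ adj2 randomi$.tw.`` scopes the whole adjacency, while a suffix
never reaches across a line reference.  Bare integers are line
references; comment lines start with ``#``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Union


class StrategyParseError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class Truncation(Enum):
    NONE = "none"
    UNLIMITED = "$"
    OPTIONAL_ONE = "?"


class Field(Enum):
    TW = "tw"  # textword: title and abstract
    PT = "pt"  # publication type


@dataclass(frozen=True)
class Term:
    stem: str
    truncation: Truncation = Truncation.NONE

    def __post_init__(self):
        if not self.stem:
            raise StrategyParseError("empty term stem")


@dataclass(frozen=True)
class Phrase:
    terms: tuple[Term, ...]

    def __post_init__(self):
        if len(self.terms) < 2:
            raise StrategyParseError("a phrase needs at least two terms")


@dataclass(frozen=True)
class Adj:
    left: Union[Term, Phrase]
    right: Union[Term, Phrase]
    window: int

    def __post_init__(self):
        if self.window < 1:
            raise StrategyParseError(f"adj window must be >= 1, got {self.window}")
        for side in (self.left, self.right):
            if not isinstance(side, (Term, Phrase)):
                raise StrategyParseError(
                    "adj operands must be single terms or phrases"
                )


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Not:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class FieldScope:
    field: Field
    expr: "Expr"


@dataclass(frozen=True)
class MeshHeading:
    heading: str


@dataclass(frozen=True)
class LineRef:
    number: int


Expr = Union[Term, Phrase, Adj, And, Or, Not, FieldScope, MeshHeading, LineRef]


def walk(expr: Expr) -> Iterator[Expr]:
    yield expr
    if isinstance(expr, (And, Or, Not, Adj)):
        yield from walk(expr.left)
        yield from walk(expr.right)
    elif isinstance(expr, FieldScope):
        yield from walk(expr.expr)
    elif isinstance(expr, Phrase):
        yield from expr.terms


def line_refs(expr: Expr) -> set[int]:
    return {n.number for n in walk(expr) if isinstance(n, LineRef)}


def _is_pure_term(expr: Expr) -> bool:
    """True when *expr* contains only term-level nodes (no refs, scopes, MeSH)."""
    return all(
        isinstance(n, (Term, Phrase, Adj, And, Or, Not)) for n in walk(expr)
    )


@dataclass(frozen=True)
class Strategy:
    """Ordered numbered query lines; the final line is the result."""

    name: str
    lines: tuple[tuple[int, Expr], ...]

    def __post_init__(self):
        if not self.lines:
            raise StrategyParseError("strategy has no lines")
        numbers = [n for n, _ in self.lines]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise StrategyParseError("line numbers must be strictly increasing")
        seen: set[int] = set()
        for number, expr in self.lines:
            for ref in line_refs(expr):
                if ref not in seen:
                    raise StrategyParseError(
                        f"reference to line {ref} not yet defined", number
                    )
            seen.add(number)

    @property
    def final_line(self) -> int:
        return self.lines[-1][0]

    @property
    def line_numbers(self) -> list[int]:
        return [n for n, _ in self.lines]

    def expr(self, number: int) -> Expr:
        for n, e in self.lines:
            if n == number:
                return e
        raise KeyError(number)


# --- lexer -----------------------------------------------------------------

_SCANNER = re.compile(
    r"""\s*(?:
      (?P<lparen>\() |
      (?P<rparen>\)) |
      (?P<suffix>\.(?P<field>[A-Za-z]{1,4})\.) |
      (?P<word>[A-Za-z][A-Za-z0-9]*[$?]?) |
      (?P<number>\d+)
    )""",
    re.VERBOSE,
)

_ADJ_RE = re.compile(r"^adj(\d*)$", re.IGNORECASE)


@dataclass(frozen=True)
class _Tok:
    kind: str  # lparen rparen suffix word number and or not adj
    value: str
    window: int = 0


def _lex(body: str, lineno: int) -> list[_Tok]:
    toks: list[_Tok] = []
    pos = 0
    while pos < len(body):
        m = _SCANNER.match(body, pos)
        if not m or m.end() == pos:
            rest = body[pos:].strip()
            if not rest:
                break
            raise StrategyParseError(f"cannot tokenize near {rest!r}", lineno)
        pos = m.end()
        if m.group("lparen"):
            toks.append(_Tok("lparen", "("))
        elif m.group("rparen"):
            toks.append(_Tok("rparen", ")"))
        elif m.group("suffix"):
            field = m.group("field").lower()
            if field not in ("tw", "pt"):
                raise StrategyParseError(f"unknown field suffix .{field}.", lineno)
            toks.append(_Tok("suffix", field))
        elif m.group("word"):
            word = m.group("word")
            low = word.lower()
            if low in ("and", "or", "not"):
                toks.append(_Tok(low, low))
            elif _ADJ_RE.match(low):
                digits = _ADJ_RE.match(low).group(1)
                toks.append(_Tok("adj", low, window=int(digits) if digits else 1))
            else:
                toks.append(_Tok("word", low))
        else:
            toks.append(_Tok("number", m.group("number")))
    return toks


# --- parser ----------------------------------------------------------------


class _LineParser:
    def __init__(self, tokens: list[_Tok], lineno: int):
        self.toks = tokens
        self.i = 0
        self.lineno = lineno

    def peek(self) -> _Tok | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise StrategyParseError("unexpected end of line", self.lineno)
        self.i += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise StrategyParseError(
                f"unexpected trailing token {self.peek().value!r}", self.lineno
            )
        return expr

    def _chain(self, sub, kinds: tuple[str, ...], build):
        left = sub()
        while (tok := self.peek()) is not None and tok.kind in kinds:
            self.next()
            right = sub()
            left = self._lift2(build, tok, left, right)
        return left

    def _lift2(self, build, tok, left, right):
        # Lift a field scope off the right operand over the whole chain
        # when the left side is pure term-level (never across LineRefs).
        if isinstance(right, FieldScope) and _is_pure_term(left) and not isinstance(left, FieldScope):
            return FieldScope(right.field, build(tok, left, right.expr))
        return build(tok, left, right)

    def parse_or(self) -> Expr:
        return self._chain(self.parse_and, ("or",), lambda t, a, b: Or(a, b))

    def parse_and(self) -> Expr:
        return self._chain(self.parse_not, ("and",), lambda t, a, b: And(a, b))

    def parse_not(self) -> Expr:
        return self._chain(self.parse_adj, ("not",), lambda t, a, b: Not(a, b))

    def parse_adj(self) -> Expr:
        def build(tok, a, b):
            if isinstance(a, FieldScope) or isinstance(b, FieldScope):
                # FieldScope on b handled by _lift2 before build is called
                raise StrategyParseError(
                    "field suffix may not appear on an inner adj operand",
                    self.lineno,
                )
            return Adj(a, b, tok.window)

        return self._chain(self.parse_primary, ("adj",), build)

    def parse_primary(self) -> Expr:
        tok = self.peek()
        if tok is None:
            raise StrategyParseError("expected a term, number or '('", self.lineno)
        if tok.kind == "number":
            self.next()
            return LineRef(int(tok.value))
        if tok.kind == "lparen":
            self.next()
            inner = self.parse_or()
            closing = self.peek()
            if closing is None or closing.kind != "rparen":
                raise StrategyParseError("missing closing parenthesis", self.lineno)
            self.next()
            return self._maybe_scope(inner)
        if tok.kind == "word":
            return self._maybe_scope(self._parse_phrase())
        raise StrategyParseError(f"unexpected token {tok.value!r}", self.lineno)

    def _parse_phrase(self) -> Expr:
        terms: list[Term] = []
        while (tok := self.peek()) is not None and tok.kind == "word":
            self.next()
            terms.append(_make_term(tok.value))
        if len(terms) == 1:
            return terms[0]
        return Phrase(tuple(terms))

    def _maybe_scope(self, expr: Expr) -> Expr:
        tok = self.peek()
        if tok is not None and tok.kind == "suffix":
            self.next()
            if not _is_pure_term(expr):
                raise StrategyParseError(
                    "a field suffix may scope only term expressions", self.lineno
                )
            return FieldScope(Field(tok.value), expr)
        return expr


def _make_term(word: str) -> Term:
    if word.endswith("$"):
        return Term(word[:-1], Truncation.UNLIMITED)
    if word.endswith("?"):
        return Term(word[:-1], Truncation.OPTIONAL_ONE)
    return Term(word)


_NUMBERED_RE = re.compile(r"^(\d+)\.\s*(.*)$")


def parse_line(number: int, body: str, lineno: int | None = None) -> Expr:
    """Parse one line body (text after ``N.``) into an expression."""
    lineno = number if lineno is None else lineno
    body = body.strip()
    if not body:
        raise StrategyParseError("empty line body", lineno)
    if body.endswith("/") and "(" not in body:
        heading = body[:-1].strip().lower()
        if not heading:
            raise StrategyParseError("empty MeSH heading", lineno)
        return MeshHeading(heading)
    tokens = _lex(body, lineno)
    expr = _LineParser(tokens, lineno).parse()
    if _is_pure_term(expr):
        raise StrategyParseError(
            "term expression must carry a field suffix (.tw./.pt.) or a "
            "trailing / for a MeSH heading",
            lineno,
        )
    _validate_scopes(expr, lineno)
    return expr


def _validate_scopes(expr: Expr, lineno: int) -> None:
    """Every term-level node must sit under exactly one field scope."""

    def check(node: Expr, scoped: bool) -> None:
        if isinstance(node, FieldScope):
            if scoped:
                raise StrategyParseError("nested field scopes", lineno)
            if not _is_pure_term(node.expr):
                raise StrategyParseError(
                    "field scope must wrap a pure term expression", lineno
                )
            if node.field is Field.PT and any(
                isinstance(inner, Adj) for inner in walk(node.expr)
            ):
                raise StrategyParseError(
                    "adj is not meaningful under whole-value .pt. matching", lineno
                )
            check(node.expr, True)
        elif isinstance(node, (Term, Phrase, Adj)):
            if not scoped:
                raise StrategyParseError(
                    "term expression outside any field scope; add .tw. or .pt.",
                    lineno,
                )
        elif isinstance(node, (And, Or, Not)):
            check(node.left, scoped)
            check(node.right, scoped)

    check(expr, False)


def parse_strategy(text: str, name: str = "strategy") -> Strategy:
    """Parse a full strategy file: numbered lines, ``#`` comments ignored.

    Raises :class:`StrategyParseError` on an empty file, a malformed line,
    or a forward/unresolved line reference (naming the line).
    """
    lines: list[tuple[int, Expr]] = []
    for raw in text.splitlines():
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _NUMBERED_RE.match(stripped)
        if not m:
            raise StrategyParseError(f"expected 'N. query', got {stripped!r}")
        number = int(m.group(1))
        lines.append((number, parse_line(number, m.group(2))))
    if not lines:
        raise StrategyParseError("strategy file contains no query lines")
    return Strategy(name=name, lines=tuple(lines))
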