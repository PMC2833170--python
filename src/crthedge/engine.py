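"""Query evaluation over a corpus.

Semantics (fixed here because historical Ovid behaviour varies by version):

* tokenization lowercases and splits on any non-alphanumeric character;
  positions are 1-based consecutive integers, no stopword removal;
* ``.tw.`` matches against the tokenized title and tokenized abstract
  independently — a pattern never matches tokens spanning the
  title/abstract boundary;
* ``.pt.`` compares whole publication-type values, case-insensitively;
* a MeSH line compares descriptors after stripping the leading ``*``
  major-topic marker and any ``/subheading`` qualifiers (no tree
  explosion: ``cluster analysis/`` is unexploded);
* ``a adjN b`` requires match start positions p, q in the same field with
  ``|p - q| <= N``, in either order;
* ``$`` is unlimited right truncation, ``?`` allows at most one extra
  character;
* Boolean lines combine earlier lines' uid sets; ``a NOT b`` is set
  difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .query import (
    Adj,
    And,
    Expr,
    Field,
    FieldScope,
    LineRef,
    MeshHeading,
    Not,
    Or,
    Phrase,
    Strategy,
    Term,
    Truncation,
)
from .records import Citation, Corpus

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase maximal alphanumeric runs; position of token i is i+1."""
    return _TOKEN_RE.findall(text.lower())


def strip_mesh(term: str) -> str:
    """Reduce a stored MeSH heading to its bare descriptor.

    ``*Health Promotion/methods`` -> ``health promotion``.
    """
    return term.lstrip("*").split("/")[0].strip().lower()


def term_matches(term: Term, token: str) -> bool:
    if term.truncation is Truncation.NONE:
        return token == term.stem
    if term.truncation is Truncation.UNLIMITED:
        return token.startswith(term.stem)
    # OPTIONAL_ONE: the stem itself or the stem plus exactly one character
    return token == term.stem or (
        len(token) == len(term.stem) + 1 and token.startswith(term.stem)
    )


def match_positions(expr: Term | Phrase, tokens: list[str]) -> list[int]:
    """1-based start positions at which a term or phrase matches."""
    if isinstance(expr, Term):
        return [i + 1 for i, tok in enumerate(tokens) if term_matches(expr, tok)]
    k = len(expr.terms)
    return [
        i + 1
        for i in range(len(tokens) - k + 1)
        if all(term_matches(t, tokens[i + j]) for j, t in enumerate(expr.terms))
    ]


def _field_match(expr: Expr, tokens: list[str]) -> bool:
    """Evaluate a pure term expression against one token list."""
    if isinstance(expr, (Term, Phrase)):
        return bool(match_positions(expr, tokens))
    if isinstance(expr, Adj):
        left = match_positions(expr.left, tokens)
        if not left:
            return False
        right = match_positions(expr.right, tokens)
        return any(abs(p - q) <= expr.window for p in left for q in right)
    if isinstance(expr, And):
        return _field_match(expr.left, tokens) and _field_match(expr.right, tokens)
    if isinstance(expr, Or):
        return _field_match(expr.left, tokens) or _field_match(expr.right, tokens)
    if isinstance(expr, Not):
        return _field_match(expr.left, tokens) and not _field_match(expr.right, tokens)
    raise TypeError(f"not a term-level node: {expr!r}")


def _pt_value_match(expr: Expr, value_tokens: list[str]) -> bool:
    """Whole-value matching of a term expression against one PT value."""
    if isinstance(expr, Term):
        return len(value_tokens) == 1 and term_matches(expr, value_tokens[0])
    if isinstance(expr, Phrase):
        return len(value_tokens) == len(expr.terms) and all(
            term_matches(t, tok) for t, tok in zip(expr.terms, value_tokens)
        )
    if isinstance(expr, And):
        return _pt_value_match(expr.left, value_tokens) and _pt_value_match(
            expr.right, value_tokens
        )
    if isinstance(expr, Or):
        return _pt_value_match(expr.left, value_tokens) or _pt_value_match(
            expr.right, value_tokens
        )
    if isinstance(expr, Not):
        return _pt_value_match(expr.left, value_tokens) and not _pt_value_match(
            expr.right, value_tokens
        )
    raise TypeError(f"unsupported node under .pt. scope: {expr!r}")


class _PreparedCitation:
    """Tokenizations computed once per citation for strategy evaluation."""

    __slots__ = ("uid", "title_tokens", "abstract_tokens", "pt_tokens", "mesh")

    def __init__(self, cit: Citation):
        self.uid = cit.uid
        self.title_tokens = tokenize(cit.title)
        self.abstract_tokens = tokenize(cit.abstract)
        self.pt_tokens = [tokenize(pt) for pt in cit.pub_types]
        self.mesh = {strip_mesh(mh) for mh in cit.mesh_terms}


def _eval_prepared(expr: Expr, doc: _PreparedCitation, prior: dict[int, set[str]]) -> bool:
    if isinstance(expr, FieldScope):
        if expr.field is Field.TW:
            return _field_match(expr.expr, doc.title_tokens) or _field_match(
                expr.expr, doc.abstract_tokens
            )
        return any(_pt_value_match(expr.expr, toks) for toks in doc.pt_tokens)
    if isinstance(expr, MeshHeading):
        return expr.heading in doc.mesh
    if isinstance(expr, LineRef):
        try:
            return doc.uid in prior[expr.number]
        except KeyError:
            raise KeyError(f"line {expr.number} not yet evaluated") from None
    if isinstance(expr, And):
        return _eval_prepared(expr.left, doc, prior) and _eval_prepared(
            expr.right, doc, prior
        )
    if isinstance(expr, Or):
        return _eval_prepared(expr.left, doc, prior) or _eval_prepared(
            expr.right, doc, prior
        )
    if isinstance(expr, Not):
        return _eval_prepared(expr.left, doc, prior) and not _eval_prepared(
            expr.right, doc, prior
        )
    raise TypeError(f"cannot evaluate node at line level: {expr!r}")


def evaluate_expression(
    expr: Expr, citation: Citation, prior: "ResultSet | dict[int, set[str]] | None" = None
) -> bool:
    """Does *citation* satisfy *expr*?  LineRefs resolve against *prior*."""
    prior_sets: dict[int, set[str]]
    if prior is None:
        prior_sets = {}
    elif isinstance(prior, ResultSet):
        prior_sets = {n: set(s) for n, s in prior.per_line.items()}
    else:
        prior_sets = prior
    return _eval_prepared(expr, _PreparedCitation(citation), prior_sets)


@dataclass(frozen=True)
class ResultSet:
    """Per-line uid sets from evaluating a strategy; final line = result."""

    per_line: dict[int, frozenset[str]]
    final_line: int

    @property
    def retrieved(self) -> frozenset[str]:
        return self.per_line[self.final_line]

    def counts(self) -> dict[int, int]:
        return {n: len(s) for n, s in self.per_line.items()}


def evaluate_strategy(strategy: Strategy, corpus: Corpus) -> ResultSet:
    """Evaluate every line in ascending order; deterministic and idempotent."""
    docs = [_PreparedCitation(c) for c in corpus]
    prior: dict[int, set[str]] = {}
    for number, expr in strategy.lines:
        prior[number] = {d.uid for d in docs if _eval_prepared(expr, d, prior)}
    return ResultSet(
        per_line={n: frozenset(s) for n, s in prior.items()},
        final_line=strategy.final_line,
    )
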