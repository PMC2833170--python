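"""Naive reference matcher used to verify the query engine.

This is a deliberately unoptimized, exhaustive re-implementation of the
strategy semantics: every citation is re-tokenized on every use, phrase and
adjacency matching enumerate all token index pairs with nested loops, and
nothing is cached.  It shares only the parsed syntax tree with the engine.
Keep it slow and obvious; its job is to be independently, visibly correct
on small corpora.
"""

from __future__ import annotations

import re

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
from .engine import ResultSet


def _toks(text: str) -> list[str]:
    out = []
    for piece in re.split(r"[^A-Za-z0-9]+", text.lower()):
        if piece != "":
            out.append(piece)
    return out


def _word_ok(term: Term, word: str) -> bool:
    if term.truncation is Truncation.UNLIMITED:
        return word[: len(term.stem)] == term.stem
    if term.truncation is Truncation.OPTIONAL_ONE:
        if word == term.stem:
            return True
        return len(word) == len(term.stem) + 1 and word[: len(term.stem)] == term.stem
    return word == term.stem


def _starts(unit: Term | Phrase, words: list[str]) -> list[int]:
    found = []
    if isinstance(unit, Term):
        for i in range(len(words)):
            if _word_ok(unit, words[i]):
                found.append(i + 1)
        return found
    for i in range(len(words)):
        ok = True
        for j in range(len(unit.terms)):
            if i + j >= len(words) or not _word_ok(unit.terms[j], words[i + j]):
                ok = False
                break
        if ok:
            found.append(i + 1)
    return found


def _term_expr_ok(expr: Expr, words: list[str]) -> bool:
    if isinstance(expr, (Term, Phrase)):
        return len(_starts(expr, words)) > 0
    if isinstance(expr, Adj):
        for p in _starts(expr.left, words):
            for q in _starts(expr.right, words):
                if p - q <= expr.window and q - p <= expr.window:
                    return True
        return False
    if isinstance(expr, And):
        return _term_expr_ok(expr.left, words) and _term_expr_ok(expr.right, words)
    if isinstance(expr, Or):
        return _term_expr_ok(expr.left, words) or _term_expr_ok(expr.right, words)
    if isinstance(expr, Not):
        return _term_expr_ok(expr.left, words) and not _term_expr_ok(expr.right, words)
    raise TypeError(expr)


def _pt_ok(expr: Expr, words: list[str]) -> bool:
    if isinstance(expr, Term):
        return len(words) == 1 and _word_ok(expr, words[0])
    if isinstance(expr, Phrase):
        if len(words) != len(expr.terms):
            return False
        for t, w in zip(expr.terms, words):
            if not _word_ok(t, w):
                return False
        return True
    if isinstance(expr, And):
        return _pt_ok(expr.left, words) and _pt_ok(expr.right, words)
    if isinstance(expr, Or):
        return _pt_ok(expr.left, words) or _pt_ok(expr.right, words)
    if isinstance(expr, Not):
        return _pt_ok(expr.left, words) and not _pt_ok(expr.right, words)
    raise TypeError(expr)


def _cit_ok(expr: Expr, cit: Citation, prior: dict[int, set[str]]) -> bool:
    if isinstance(expr, FieldScope):
        if expr.field is Field.TW:
            return _term_expr_ok(expr.expr, _toks(cit.title)) or _term_expr_ok(
                expr.expr, _toks(cit.abstract)
            )
        for value in cit.pub_types:
            if _pt_ok(expr.expr, _toks(value)):
                return True
        return False
    if isinstance(expr, MeshHeading):
        for raw in cit.mesh_terms:
            descriptor = raw
            while descriptor.startswith("*"):
                descriptor = descriptor[1:]
            descriptor = descriptor.split("/")[0].strip().lower()
            if descriptor == expr.heading:
                return True
        return False
    if isinstance(expr, LineRef):
        return cit.uid in prior[expr.number]
    if isinstance(expr, And):
        return _cit_ok(expr.left, cit, prior) and _cit_ok(expr.right, cit, prior)
    if isinstance(expr, Or):
        return _cit_ok(expr.left, cit, prior) or _cit_ok(expr.right, cit, prior)
    if isinstance(expr, Not):
        return _cit_ok(expr.left, cit, prior) and not _cit_ok(expr.right, cit, prior)
    raise TypeError(expr)


def oracle_match(strategy: Strategy, corpus: Corpus) -> ResultSet:
    """Same contract as :func:`crthedge.engine.evaluate_strategy`."""
    prior: dict[int, set[str]] = {}
    for number, expr in strategy.lines:
        hit: set[str] = set()
        for cit in corpus:
            if _cit_ok(expr, cit, prior):
                hit.add(cit.uid)
        prior[number] = hit
    return ResultSet(
        per_line={n: frozenset(s) for n, s in prior.items()},
        final_line=strategy.final_line,
    )
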