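"""Random strategy and corpus generation for engine/oracle agreement tests.

Strategies are drawn from the same grammar the parser accepts: term lines
scoped to .tw. or .pt., MeSH heading lines, and Boolean combinations of
earlier lines.  The vocabulary deliberately contains shared prefixes
("cluster", "clusters", "clustering") so truncation and the one-extra-
character wildcard are exercised, and corpora are token soups over the
same vocabulary so matches are neither guaranteed nor vanishing.
"""

from __future__ import annotations

import numpy as np

from crthedge.query import (
    Adj,
    And,
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
from crthedge.records import Citation, Corpus

VOCAB = [
    "cluster", "clusters", "clustering", "random", "randomised", "randomized",
    "randomization", "trial", "trials", "school", "schools", "community",
    "intervention", "interventions", "interventional", "care", "health",
    "group", "groups", "patient", "patients", "outcome", "ward", "wards",
]
MESH_POOL = ["cluster analysis", "health promotion", "program evaluation", "humans"]
PT_POOL = ["Journal Article", "Randomized Controlled Trial", "Review"]


def random_term(rng: np.random.Generator) -> Term:
    word = VOCAB[int(rng.integers(len(VOCAB)))]
    r = rng.random()
    if r < 0.4:
        return Term(word)
    if r < 0.7:
        cut = int(rng.integers(3, len(word) + 1))
        return Term(word[:cut], Truncation.UNLIMITED)
    cut = int(rng.integers(max(3, len(word) - 1), len(word) + 1))
    return Term(word[:cut], Truncation.OPTIONAL_ONE)


def random_unit(rng: np.random.Generator):
    if rng.random() < 0.3:
        return Phrase((random_term(rng), random_term(rng)))
    return random_term(rng)


def random_term_expr(rng: np.random.Generator, depth: int, allow_adj: bool = True):
    if depth <= 0 or rng.random() < 0.4:
        if allow_adj and rng.random() < 0.35:
            return Adj(random_unit(rng), random_unit(rng), int(rng.integers(1, 4)))
        return random_unit(rng)
    op = (And, Or, Not)[int(rng.integers(3))]
    return op(
        random_term_expr(rng, depth - 1, allow_adj),
        random_term_expr(rng, depth - 1, allow_adj),
    )


def random_strategy(rng: np.random.Generator, n_lines: int = 6) -> Strategy:
    lines = []
    numbers: list[int] = []
    for i in range(n_lines):
        number = i + 1
        can_ref = len(numbers) >= 2
        roll = rng.random()
        if can_ref and roll < 0.4:
            refs = rng.choice(numbers, size=2, replace=True)
            op = (And, Or, Not)[int(rng.integers(3))]
            expr = op(LineRef(int(refs[0])), LineRef(int(refs[1])))
        elif roll < 0.55:
            expr = MeshHeading(MESH_POOL[int(rng.integers(len(MESH_POOL)))])
        else:
            field = Field.PT if rng.random() < 0.2 else Field.TW
            depth = int(rng.integers(0, 3))
            expr = FieldScope(
                field, random_term_expr(rng, depth, allow_adj=field is Field.TW)
            )
        lines.append((number, expr))
        numbers.append(number)
    return Strategy(name="random", lines=tuple(lines))


def random_corpus(rng: np.random.Generator, n: int = 40) -> Corpus:
    citations = []
    for i in range(n):
        title_words = rng.choice(VOCAB, size=int(rng.integers(2, 8)))
        abstract_words = rng.choice(VOCAB, size=int(rng.integers(0, 30)))
        n_mesh = int(rng.integers(0, 3))
        mesh = []
        for _ in range(n_mesh):
            heading = MESH_POOL[int(rng.integers(len(MESH_POOL)))].title()
            if rng.random() < 0.3:
                heading = "*" + heading
            if rng.random() < 0.3:
                heading += "/methods"
            mesh.append(heading)
        pts = [PT_POOL[int(rng.integers(len(PT_POOL)))]]
        citations.append(
            Citation(
                uid=f"{90000000 + i:08d}",
                title=" ".join(title_words),
                abstract=" ".join(abstract_words),
                mesh_terms=mesh,
                pub_types=pts,
                year=int(rng.integers(2000, 2008)),
            )
        )
    return Corpus(citations)
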