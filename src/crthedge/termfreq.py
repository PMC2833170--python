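"""Frequency analysis of textwords and MeSH descriptors.

Used when building a new filter: rank candidate terms by how much more
often they occur among the relevant articles than in the rest of the
corpus.  Counts are per-document presence (a term counted once per
citation; a MeSH descriptor once regardless of subheadings or major-topic
markers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import strip_mesh, tokenize
from .records import Corpus


def term_frequency(corpus: Corpus, relevant: set[str]) -> pd.DataFrame:
    """Ranked term table contrasting the relevant set with its complement.

    Columns: ``term``, ``kind`` ("textword" or "mesh"), ``relevant_count``,
    ``other_count``, ``ratio`` (relative document frequency in the relevant
    set over that in the complement; ``inf`` when the term never occurs in
    the complement).  Sorted by ratio, then relevant count, both
    descending, ties broken alphabetically.  Raises on an empty relevant
    set or relevant uids missing from the corpus.
    """
    if not relevant:
        raise ValueError("relevant set is empty")
    missing = [u for u in relevant if u not in corpus]
    if missing:
        raise ValueError(f"relevant uids not in corpus: {sorted(missing)[:5]}")

    n_rel = len(relevant)
    n_other = len(corpus) - n_rel

    counts: dict[tuple[str, str], list[int]] = {}
    for cit in corpus:
        is_rel = cit.uid in relevant
        seen = {("textword", tok) for tok in tokenize(cit.title)}
        seen |= {("textword", tok) for tok in tokenize(cit.abstract)}
        seen |= {("mesh", strip_mesh(mh)) for mh in cit.mesh_terms}
        for key in seen:
            cell = counts.setdefault(key, [0, 0])
            cell[0 if is_rel else 1] += 1

    rows = []
    for (kind, term), (rel_count, other_count) in counts.items():
        rel_freq = rel_count / n_rel
        if other_count == 0 or n_other == 0:
            ratio = np.inf if rel_count > 0 else 0.0
        else:
            ratio = rel_freq / (other_count / n_other)
        rows.append((term, kind, rel_count, other_count, ratio))

    df = pd.DataFrame(
        rows, columns=["term", "kind", "relevant_count", "other_count", "ratio"]
    )
    df = df.sort_values(
        by=["ratio", "relevant_count", "term"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
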