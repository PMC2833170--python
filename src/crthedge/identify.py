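"""Classify how a cluster randomized trial reveals its design in text.

Three-way verdict on a citation's title and abstract:

* ``CLEAR`` — an explicit design phrase: a design noun (cluster, group,
  community, singular or plural) immediately followed by a
  randomis*/randomiz* token.  Hyphens and spelling variants are tolerated
  because tokenization splits on punctuation ("cluster-randomised" and
  "cluster randomized" look identical).
* ``UNIT`` — no design phrase, but a unit-of-randomization noun (school,
  practice, hospital, ...) co-occurs within a small token window of a
  randomization pattern ("schools were randomized", "randomization by
  practice", "villages were randomly allocated").
* ``NONE`` — neither signal; the design is only discoverable in the full
  text.

The unit-noun lexicon and the window size are configuration, not
constants: cluster units are open-ended (football teams, churches,
household clusters...), so reviewers can extend the lexicon to their
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import tokenize
from .records import Citation, Identifiability

_DESIGN_NOUNS = {"cluster", "clusters", "group", "groups", "community", "communities"}

#: Unit nouns shipped by default (singular and plural forms).
DEFAULT_UNIT_NOUNS = frozenset(
    {
        "school", "schools",
        "physician", "physicians",
        "practice", "practices",
        "hospital", "hospitals",
        "community", "communities",
        "village", "villages",
        "ward", "wards",
        "team", "teams",
        "church", "churches",
    }
)

_ALLOC_PREFIXES = ("allocat", "assign")


@dataclass(frozen=True)
class IdentifiabilityConfig:
    """Tunables for the classifier.

    ``window``: maximum token distance between a unit noun and a
    randomization pattern for the UNIT verdict (default 4 — wide enough
    for "patients were randomized by physician", narrow enough not to
    sweep up unrelated mentions).
    """

    window: int = 4
    unit_nouns: frozenset[str] = DEFAULT_UNIT_NOUNS

    def with_extra_nouns(self, *nouns: str) -> "IdentifiabilityConfig":
        return IdentifiabilityConfig(
            window=self.window,
            unit_nouns=self.unit_nouns | {n.lower() for n in nouns},
        )


DEFAULT_CONFIG = IdentifiabilityConfig()


def _is_randomi(token: str) -> bool:
    return token.startswith(("randomis", "randomiz"))


def _has_clear_phrase(tokens: list[str]) -> bool:
    return any(
        tok in _DESIGN_NOUNS and _is_randomi(tokens[i + 1])
        for i, tok in enumerate(tokens[:-1])
    )


def _randomization_positions(tokens: list[str]) -> list[int]:
    """1-based positions of randomization anchors.

    Anchors: any randomis*/randomiz* token, or random/randomly followed by
    an allocat*/assign* token.
    """
    anchors = []
    for i, tok in enumerate(tokens):
        if _is_randomi(tok):
            anchors.append(i + 1)
        elif tok in ("random", "randomly"):
            if i + 1 < len(tokens) and tokens[i + 1].startswith(_ALLOC_PREFIXES):
                anchors.append(i + 1)
    return anchors


def _has_unit_pattern(tokens: list[str], config: IdentifiabilityConfig) -> bool:
    anchors = _randomization_positions(tokens)
    if not anchors:
        return False
    noun_positions = [
        i + 1 for i, tok in enumerate(tokens) if tok in config.unit_nouns
    ]
    return any(
        abs(p - q) <= config.window for p in anchors for q in noun_positions
    )


def classify_identifiability(
    citation: Citation, config: IdentifiabilityConfig = DEFAULT_CONFIG
) -> Identifiability:
    """CLEAR, UNIT or NONE from title and abstract (fields scanned separately)."""
    fields = [tokenize(citation.title), tokenize(citation.abstract)]
    if any(_has_clear_phrase(toks) for toks in fields):
        return Identifiability.CLEAR
    if any(_has_unit_pattern(toks, config) for toks in fields):
        return Identifiability.UNIT
    return Identifiability.NONE
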