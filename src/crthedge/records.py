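"""Core record types: citations, corpora and gold-standard labels.

A :class:`Citation` is one bibliographic record as exported from MEDLINE
(title, abstract, MeSH headings, publication types, journal, year), a
:class:`Corpus` is an ordered, uid-unique collection of citations, and
:class:`GoldLabels` carries the hand-search verdict for each citation:
whether it reports a cluster randomized trial (CRT) and, if so, how the
clustered design can be recognised from the title or abstract.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator


class ValidationError(ValueError):
    """Raised when a record, corpus or label set violates an invariant."""


class Identifiability(str, Enum):
    """How a CRT can be recognised from its title or abstract.

    CLEAR
        An explicit design phrase ("cluster randomized", "group
        randomized", "community randomized") appears in title or abstract.
    UNIT
        Only the unit of randomization gives it away (e.g. "schools were
        randomized", "randomization by practice").
    NONE
        Not identifiable from title/abstract; full text needed.
    NA
        Not applicable (the article is not a CRT).
    """

    CLEAR = "CLEAR"
    UNIT = "UNIT"
    NONE = "NONE"
    NA = "NA"


_UID_RE = re.compile(r"^\d{8}$")


@dataclass
class Citation:
    """One bibliographic record.

    ``mesh_terms`` are stored exactly as indexed: a heading may carry a
    leading major-topic marker ``*`` and one or more ``/subheading``
    qualifiers.  ``year`` is the publication year, or ``None`` if unknown.
    """

    uid: str
    title: str
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    pub_types: list[str] = field(default_factory=list)
    journal: str = ""
    year: int | None = None

    def validate(self) -> None:
        if not self.uid:
            raise ValidationError("citation uid must be non-empty")
        if not self.title:
            raise ValidationError(f"citation {self.uid!r}: title must be non-empty")
        if self.year is not None and not 1900 <= self.year <= 2100:
            raise ValidationError(
                f"citation {self.uid!r}: year {self.year} outside [1900, 2100]"
            )
        if not _UID_RE.match(self.uid):
            warnings.warn(
                f"uid {self.uid!r} is not the canonical 8-digit form",
                stacklevel=2,
            )


class Corpus:
    """Ordered collection of citations with unique uids.

    Iteration order is the insertion order and is stable; lookup by uid is
    O(1).
    """

    def __init__(self, citations: list[Citation] | None = None, provenance: str = ""):
        self.provenance = provenance
        self._citations: list[Citation] = []
        self._by_uid: dict[str, Citation] = {}
        for cit in citations or []:
            self.add(cit)

    def add(self, citation: Citation) -> None:
        citation.validate()
        if citation.uid in self._by_uid:
            raise ValidationError(f"duplicate uid in corpus: {citation.uid}")
        self._citations.append(citation)
        self._by_uid[citation.uid] = citation

    def __iter__(self) -> Iterator[Citation]:
        return iter(self._citations)

    def __len__(self) -> int:
        return len(self._citations)

    def __contains__(self, uid: str) -> bool:
        return uid in self._by_uid

    def __getitem__(self, uid: str) -> Citation:
        return self._by_uid[uid]

    @property
    def uids(self) -> list[str]:
        return [c.uid for c in self._citations]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._citations == other._citations


@dataclass(frozen=True)
class LabelRecord:
    """Gold-standard verdict for a single citation."""

    is_crt: bool
    identifiability: Identifiability
    year: int

    def __post_init__(self) -> None:
        if self.identifiability is not Identifiability.NA and not self.is_crt:
            raise ValidationError(
                f"identifiability {self.identifiability.value} requires is_crt=True"
            )
        if self.is_crt and self.identifiability is Identifiability.NA:
            raise ValidationError("a CRT label must carry an identifiability class")


class GoldLabels:
    """Per-uid gold-standard labels for a corpus."""

    def __init__(self, records: dict[str, LabelRecord] | None = None):
        self._records: dict[str, LabelRecord] = dict(records or {})

    def add(self, uid: str, record: LabelRecord) -> None:
        if uid in self._records:
            raise ValidationError(f"duplicate uid in labels: {uid}")
        self._records[uid] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, uid: str) -> bool:
        return uid in self._records

    def __getitem__(self, uid: str) -> LabelRecord:
        return self._records[uid]

    def items(self):
        return self._records.items()

    @property
    def uids(self) -> list[str]:
        return list(self._records)

    def crt_uids(self) -> set[str]:
        return {u for u, r in self._records.items() if r.is_crt}

    def class_counts(self) -> dict[Identifiability, int]:
        """Number of CRTs per identifiability class (NA excluded)."""
        counts = {c: 0 for c in (Identifiability.CLEAR, Identifiability.UNIT, Identifiability.NONE)}
        for rec in self._records.values():
            if rec.is_crt:
                counts[rec.identifiability] += 1
        return counts

    def check_against(self, corpus: Corpus) -> list[str]:
        """Return uids labelled here but absent from *corpus*.

        Unmatched labels are reported to the caller, never dropped
        silently; evaluation code must refuse to proceed when this list is
        non-empty unless the caller explicitly subsets.
        """
        return [u for u in self._records if u not in corpus]
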