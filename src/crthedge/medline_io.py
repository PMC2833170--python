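"""Reading and writing MEDLINE tagged-format corpora and label files.

The tagged ("nbib") dialect accepted here is the common export form: one
``TAG - content`` line per field, continuation lines indented, records
separated by blank lines.  Both the padded 4-character tag form
(``TI  - ``) and the unpadded form (``TI- ``) are accepted on input; the
padded form is emitted on output, so write → read is the identity.

Label files are comma- or tab-delimited text with header
``uid,is_crt,identifiability,year``.
"""

from __future__ import annotations

import csv
import io
import os
import re
from typing import IO, Iterable

from .records import (
    Citation,
    Corpus,
    GoldLabels,
    Identifiability,
    LabelRecord,
    ValidationError,
)


class MedlineParseError(ValueError):
    """Malformed tagged-format input; message names the offending line."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s*-\s?(.*)$")
_WS_RE = re.compile(r"\s+")

# Tags we map onto Citation fields; PMID starts a new record.  Unknown tags
# are skipped (OVID exports carry many fields beyond the ones used here).
_REPEAT_TAGS = {"MH", "PT"}


def _collapse(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def _year_from_dp(dp: str) -> int | None:
    m = re.search(r"\b(\d{4})\b", dp)
    return int(m.group(1)) if m else None


def _open_source(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8", errors="replace"), True


def read_medline(source) -> Corpus:
    """Parse a MEDLINE tagged-format stream or file path into a Corpus.

    Multi-line fields are joined with single spaces (internal whitespace
    collapsed); repeated ``MH`` and ``PT`` tags accumulate in file order;
    a record without an ``AB`` tag yields an empty abstract.

    Raises :class:`MedlineParseError` naming the line number on a
    malformed tag line, and :class:`~crthedge.records.ValidationError` on
    duplicate uids.
    """
    handle, close = _open_source(source)
    try:
        fields: list[tuple[str, str]] = []
        records: list[list[tuple[str, str]]] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                if fields:
                    records.append(fields)
                    fields = []
                continue
            if line[0].isspace():
                if not fields:
                    raise MedlineParseError(
                        "continuation line before any tag line", lineno
                    )
                tag, value = fields[-1]
                fields[-1] = (tag, value + " " + line.strip())
                continue
            m = _TAG_RE.match(line)
            if not m:
                raise MedlineParseError(f"malformed tag line: {line!r}", lineno)
            tag, content = m.group(1), m.group(2)
            if tag == "PMID" and fields:
                records.append(fields)
                fields = []
            fields.append((tag, content))
        if fields:
            records.append(fields)
    finally:
        if close:
            handle.close()

    corpus = Corpus(provenance="read_medline")
    for rec_fields in records:
        cit = Citation(uid="", title="")
        for tag, value in rec_fields:
            value = _collapse(value)
            if tag == "PMID":
                cit.uid = value
            elif tag == "TI":
                cit.title = value
            elif tag == "AB":
                cit.abstract = value
            elif tag == "JT":
                cit.journal = value
            elif tag == "DP":
                cit.year = _year_from_dp(value)
            elif tag == "MH":
                cit.mesh_terms.append(value)
            elif tag == "PT":
                cit.pub_types.append(value)
            # other tags: ignored
        corpus.add(cit)
    return corpus


def write_medline(corpus: Corpus, sink) -> int:
    """Write *corpus* in padded tagged format; returns the record count.

    Output is bit-deterministic for a given corpus and re-readable by
    :func:`read_medline` with field-level equality.
    """
    if hasattr(sink, "write"):
        return _write_medline(corpus, sink)
    with open(os.fspath(sink), "w", encoding="utf-8") as handle:
        return _write_medline(corpus, handle)


def _write_medline(corpus: Corpus, handle: IO[str]) -> int:
    n = 0
    for cit in corpus:
        if n:
            handle.write("\n")
        _emit(handle, "PMID", cit.uid)
        _emit(handle, "TI", cit.title)
        if cit.abstract:
            _emit(handle, "AB", cit.abstract)
        if cit.journal:
            _emit(handle, "JT", cit.journal)
        if cit.year is not None:
            _emit(handle, "DP", str(cit.year))
        for mh in cit.mesh_terms:
            _emit(handle, "MH", mh)
        for pt in cit.pub_types:
            _emit(handle, "PT", pt)
        n += 1
    return n


def _emit(handle: IO[str], tag: str, value: str) -> None:
    handle.write(f"{tag:<4}- {value}\n")


def corpus_to_text(corpus: Corpus) -> str:
    buf = io.StringIO()
    write_medline(corpus, buf)
    return buf.getvalue()


_LABEL_HEADER = ["uid", "is_crt", "identifiability", "year"]
_TRUE_TOKENS = {"true", "1", "yes"}
_FALSE_TOKENS = {"false", "0", "no"}


def read_labels(source) -> GoldLabels:
    """Read a delimited label file (header ``uid,is_crt,identifiability,year``).

    A missing identifiability for a non-CRT maps to NA; an unknown enum
    token, or a non-CRT carrying a class, is a validation error.
    """
    handle, close = _open_source(source)
    try:
        first = handle.readline()
        if not first.strip():
            raise ValidationError("empty label file")
        delim = "\t" if "\t" in first else ","
        reader = csv.reader(
            [first] + handle.read().splitlines(), delimiter=delim
        )
        rows = list(reader)
    finally:
        if close:
            handle.close()

    header = [h.strip().lower() for h in rows[0]]
    if header != _LABEL_HEADER:
        raise ValidationError(
            f"label header must be {','.join(_LABEL_HEADER)}, got {','.join(header)}"
        )
    labels = GoldLabels()
    for row in rows[1:]:
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != 4:
            raise ValidationError(f"label row has {len(row)} fields, expected 4: {row}")
        uid, crt_tok, ident_tok, year_tok = (cell.strip() for cell in row)
        crt_low = crt_tok.lower()
        if crt_low in _TRUE_TOKENS:
            is_crt = True
        elif crt_low in _FALSE_TOKENS:
            is_crt = False
        else:
            raise ValidationError(f"uid {uid}: unknown is_crt token {crt_tok!r}")
        if not ident_tok:
            if is_crt:
                raise ValidationError(f"uid {uid}: CRT row lacks identifiability class")
            ident = Identifiability.NA
        else:
            try:
                ident = Identifiability(ident_tok.upper())
            except ValueError:
                raise ValidationError(
                    f"uid {uid}: unknown identifiability token {ident_tok!r}"
                ) from None
        try:
            record = LabelRecord(is_crt=is_crt, identifiability=ident, year=int(year_tok))
        except ValueError as exc:
            raise ValidationError(f"uid {uid}: {exc}") from None
        labels.add(uid, record)
    return labels


def write_labels(labels: GoldLabels, sink, delimiter: str = ",") -> int:
    """Write labels in the delimited form accepted by :func:`read_labels`."""
    if hasattr(sink, "write"):
        return _write_labels(labels, sink, delimiter)
    with open(os.fspath(sink), "w", encoding="utf-8", newline="") as handle:
        return _write_labels(labels, handle, delimiter)


def _write_labels(labels: GoldLabels, handle: IO[str], delimiter: str) -> int:
    writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
    writer.writerow(_LABEL_HEADER)
    n = 0
    for uid, rec in labels.items():
        ident = "" if rec.identifiability is Identifiability.NA else rec.identifiability.value
        writer.writerow([uid, "true" if rec.is_crt else "false", ident, rec.year])
        n += 1
    return n
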