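"""The canonical CRT search filters, shipped as named built-ins.

Six strategies cover the published filter family for retrieving cluster
randomized trials from MEDLINE:

* ``rct_pt`` — the classic "simple strategy for the busy searcher":
  publication type "randomized controlled trial", minus animal-only
  records;
* ``cluster_terms`` — explicit cluster/community/group design phrases;
* ``broad_terms`` — broad intervention textword plus four MeSH headings
  common in cluster-randomized research;
* ``combined_terms`` — union of the two term blocks;
* ``highest_sensitivity`` — combined terms OR the publication-type filter;
* ``highest_precision`` — combined terms AND the publication-type filter.

The strategy text is packaged verbatim (including the animal-exclusion
subexpression ``2 NOT (2 AND 3)``); line numbering follows the published
18-line layout so cross-references stay recognisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .query import Strategy, parse_strategy


@dataclass(frozen=True)
class BuiltinInfo:
    name: str
    filename: str
    description: str


_REGISTRY: tuple[BuiltinInfo, ...] = (
    BuiltinInfo(
        "rct_pt",
        "rct_pt.txt",
        "Publication-type filter for randomized controlled trials (lines 1-5)",
    ),
    BuiltinInfo(
        "cluster_terms",
        "cluster_terms.txt",
        "Cluster design-related textwords (lines 6-9)",
    ),
    BuiltinInfo(
        "broad_terms",
        "broad_terms.txt",
        "Broad intervention textword and MeSH headings (lines 10-15)",
    ),
    BuiltinInfo(
        "combined_terms",
        "combined_terms.txt",
        "Union of cluster and broad term blocks (lines 6-16)",
    ),
    BuiltinInfo(
        "highest_sensitivity",
        "highest_sensitivity.txt",
        "Combined terms OR publication-type filter (lines 1-17)",
    ),
    BuiltinInfo(
        "highest_precision",
        "highest_precision.txt",
        "Combined terms AND publication-type filter (lines 1-16, 18)",
    ),
)

_BY_NAME = {info.name: info for info in _REGISTRY}


class UnknownBuiltinError(KeyError):
    def __init__(self, name: str):
        available = ", ".join(info.name for info in _REGISTRY)
        super().__init__(f"unknown builtin {name!r}; available: {available}")


def builtin_text(name: str) -> str:
    """Verbatim packaged text of a built-in strategy."""
    try:
        info = _BY_NAME[name]
    except KeyError:
        raise UnknownBuiltinError(name) from None
    return (
        resources.files("crthedge").joinpath("strategies", info.filename).read_text(
            encoding="utf-8"
        )
    )


def builtin_strategy(name: str) -> Strategy:
    """Parse and return a named built-in strategy."""
    return parse_strategy(builtin_text(name), name=name)


def list_builtins() -> list[BuiltinInfo]:
    """All registry entries, in stable order."""
    return list(_REGISTRY)
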