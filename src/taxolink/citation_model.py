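"""Citations at two granularities: microcitations and works.

Nomenclators record where a name was published as a *microcitation* — a
terse pointer to a page within a publication, e.g. ``IMA Fungus 83: 166
(2021)`` — rather than a full bibliographic citation.  This module parses
such strings into structured fields, normalizes publication-venue
("container") names through an alias table, and renders full citation
strings from work-level metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import MissingFieldError, ParseFailureError
from .identifiers import LSID, PersistentIdentifier

__all__ = [
    "MicroCitation",
    "Work",
    "NameRecord",
    "SourceDb",
    "AliasTable",
    "parse_microcitation",
    "normalize_container",
    "format_citation",
]


class SourceDb(str, Enum):
    INDEX_FUNGORUM = "IndexFungorum"
    IPNI = "IPNI"
    ION = "ION"
    OTHER = "other"


@dataclass(frozen=True)
class MicroCitation:
    """Parsed fields of a page-level citation string.

    ``raw`` is preserved verbatim.  ``page`` (sequential pagination) and
    ``article_number`` (continuous article numbering) are mutually
    exclusive outcomes of one parse.
    """

    raw: str
    container: str
    authors: Optional[str] = None
    volume: Optional[str] = None
    issue: Optional[str] = None
    page: Optional[int] = None
    article_number: Optional[str] = None
    year: Optional[int] = None

    def __post_init__(self):
        if self.page is not None and self.article_number is not None:
            raise ValueError("page and article_number are mutually exclusive")


@dataclass
class Work:
    """A work-level bibliographic record (the unit normally cited)."""

    work_id: str
    container: str
    volume: Optional[str] = None
    issue: Optional[str] = None
    page_start: Optional[int] = None
    page_end: Optional[int] = None
    year: Optional[int] = None
    title: Optional[str] = None
    authors: Sequence[str] = field(default_factory=tuple)
    identifiers: frozenset = field(default_factory=frozenset)
    article_number: Optional[str] = None

    def __post_init__(self):
        if (self.page_start is not None and self.page_end is not None
                and self.page_start > self.page_end):
            raise ValueError(f"page_start > page_end in work {self.work_id}")
        self.identifiers = frozenset(self.identifiers)


@dataclass
class NameRecord:
    """A taxonomic name with its LSID and the microcitation of its publication."""

    lsid: LSID
    name_string: str
    microcitation: MicroCitation
    rank: Optional[str] = None
    source_db: SourceDb = SourceDb.OTHER

    def __post_init__(self):
        if not self.name_string:
            raise ValueError("name_string must be non-empty")


def _fold(name: str) -> str:
    """Case/punctuation/whitespace-insensitive key for container lookup."""
    return re.sub(r"\s+", " ", re.sub(r"[^\w\s]", " ", name).strip().lower())


class AliasTable:
    """Maps container-name variants (abbreviations, case variants) to a
    canonical venue name.

    Built from (alias, canonical) pairs; every canonical name is also
    self-registered so that normalization is idempotent.  Lookup folds
    case, punctuation and whitespace.
    """

    def __init__(self, pairs: Mapping[str, str] | Sequence[tuple[str, str]] = ()):
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        self._map: dict[str, str] = {}
        for alias, canonical in items:
            self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        self._map[_fold(alias)] = canonical
        self._map.setdefault(_fold(canonical), canonical)

    def canonical(self, name: str) -> Optional[str]:
        return self._map.get(_fold(name))

    @classmethod
    def from_tsv(cls, path) -> "AliasTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                alias, canonical = line.split("\t")[:2]
                table.add(alias, canonical)
        return table


def normalize_container(name: str, aliases: Optional[AliasTable] = None) -> str:
    """Canonicalize a container name.

    Known aliases map to their canonical venue name; unknown names are
    returned whitespace-trimmed/collapsed with original casing.  Idempotent.
    """
    cleaned = re.sub(r"\s+", " ", name).strip()
    if aliases is not None:
        hit = aliases.canonical(cleaned)
        if hit is not None:
            return hit
    return cleaned


# Microcitation grammar: an ordered alternation, first match wins.
# Leading text before the container is treated as the author block.
#
#   1. "<container>, volume <v>, issue no. <n>"   (continuous numbering)
#   2. "<container> <volume> (<issue>): <page> [(<year>)]"
#   3. "<container> <volume>: <page> [(<year>)]"
_PAT_ISSUE_NO = re.compile(
    r"^(?:(?P<authors>.*?),\s*)??(?P<container>[^,]+?),\s*volume\s+(?P<volume>\S+?),?\s*"
    r"issue\s+no\.?\s*(?P<artnum>\S+?)\.?\s*(?:\((?P<year>\d{4})\))?\s*$",
    re.IGNORECASE)
_PAT_VOL_ISSUE_PAGE = re.compile(
    r"^(?:(?P<authors>.*),\s*)?(?P<container>[^,:()]+?)\s+(?P<volume>\S+)\s*"
    r"\((?P<issue>[^)]+)\)\s*:\s*(?P<page>\S+?),?\s*(?:\((?P<year>\d{4})\))?\s*$")
_PAT_VOL_PAGE = re.compile(
    r"^(?:(?P<authors>.*),\s*)?(?P<container>[^,:()]+?)\s+(?P<volume>\S+)\s*"
    r":\s*(?P<page>\S+?),?\s*(?:\((?P<year>\d{4})\))?\s*$")

_PAGE_RE = re.compile(r"^\d+$")


def parse_microcitation(text: str, aliases: Optional[AliasTable] = None) -> MicroCitation:
    """Parse a microcitation string into structured fields.

    Page tokens that are not plain integers (Roman numerals, plate
    references) are left in the author/residue block rather than guessed.
    Raises :class:`ParseFailureError` when no pattern matches.
    """
    if not text or not text.strip():
        raise ParseFailureError(text, "empty microcitation")
    raw = text
    stripped = text.strip()
    for pat in (_PAT_ISSUE_NO, _PAT_VOL_ISSUE_PAGE, _PAT_VOL_PAGE):
        m = pat.match(stripped)
        if m is None:
            continue
        g = m.groupdict()
        authors = (g.get("authors") or "").strip(" ,") or None
        page = None
        artnum = g.get("artnum")
        page_tok = g.get("page")
        if page_tok is not None:
            if _PAGE_RE.match(page_tok):
                page = int(page_tok)
            else:
                # keep unparsed page tokens (e.g. "xii", "pl. 4") as residue
                authors = f"{authors} [{page_tok}]" if authors else f"[{page_tok}]"
        container = normalize_container(g["container"], aliases)
        year = int(g["year"]) if g.get("year") else None
        return MicroCitation(
            raw=raw, container=container, authors=authors,
            volume=g.get("volume"), issue=g.get("issue"),
            page=page, article_number=artnum, year=year,
        )
    raise ParseFailureError(raw)


def format_citation(work: Work, style: str = "author-year") -> str:
    """Render a deterministic human-readable citation for a work.

    One built-in author–year style:
    ``Author1, Author2 (Year) Title. Container Volume: Start–End.``
    Segments for absent optional fields are dropped; container and year are
    required.
    """
    if style != "author-year":
        raise ValueError(f"unknown citation style: {style!r}")
    missing = [f for f in ("container", "year") if getattr(work, f) in (None, "")]
    if missing:
        raise MissingFieldError(missing)
    parts = []
    if work.authors:
        parts.append(", ".join(work.authors) + " ")
    parts.append(f"({work.year}) ")
    if work.title:
        parts.append(work.title.rstrip(".") + ". ")
    parts.append(work.container)
    if work.volume:
        parts.append(f" {work.volume}")
        if work.issue:
            parts.append(f" ({work.issue})")
    if work.page_start is not None:
        pages = str(work.page_start)
        if work.page_end is not None and work.page_end != work.page_start:
            pages += f"–{work.page_end}"
        parts.append(f": {pages}")
    elif work.article_number:
        parts.append(f": {work.article_number}")
    return "".join(parts) + "."
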