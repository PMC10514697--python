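"""Persistent identifiers used in taxonomic literature linking.

Taxonomic name databases (nomenclators) mint Life Science Identifiers
(LSIDs) for names, while the publications that make those names available
carry a mixed bag of work-level identifiers: DOIs, Handles, JSTOR/BioStor/BHL
links, plain URLs, PDF links and Wikidata item ids (QIDs).  This module
parses, normalizes, compares and ranks them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import EmptySetError, MalformedIdentifierError

__all__ = [
    "LSID",
    "IdKind",
    "PersistentIdentifier",
    "FragmentIdentifier",
    "parse_lsid",
    "normalize_doi",
    "classify_url",
    "lsids_equivalent",
    "preferred_identifier",
    "DEFAULT_PRECEDENCE",
    "DEFAULT_EQUIVALENCE_RULES",
]


@dataclass(frozen=True, order=True)
class LSID:
    """A Life Science Identifier, ``urn:lsid:authority:namespace:object[:revision]``.

    The authority is a DNS name and is case-insensitive; it is folded to
    lower case on construction so that parse/serialize round-trips are
    stable.
    """

    authority: str
    namespace: str
    object_id: str
    revision: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "authority", self.authority.lower())

    def __str__(self) -> str:
        parts = ["urn:lsid", self.authority, self.namespace, self.object_id]
        if self.revision is not None:
            parts.append(self.revision)
        return ":".join(parts)


class IdKind(str, Enum):
    """The work-level identifier kinds tracked per publication."""

    DOI = "DOI"
    HANDLE = "Handle"
    JSTOR = "JSTOR"
    BIOSTOR = "BioStor"
    BHL = "BHL"
    URL = "URL"
    PDF = "PDF"
    WIKIDATA = "WikidataQID"


@dataclass(frozen=True, order=True)
class PersistentIdentifier:
    """A typed work-level identifier with a canonical comparison value.

    ``value`` is the canonical form (DOIs: bare ``10.x/...`` lower-cased;
    QIDs: ``Q`` + digits).  ``display`` preserves the original casing for
    presentation; it never participates in equality.
    """

    kind: IdKind
    value: str
    display: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.display:
            object.__setattr__(self, "display", self.value)
        if self.kind is IdKind.WIKIDATA and not re.fullmatch(r"Q\d+", self.value):
            raise MalformedIdentifierError(f"not a Wikidata QID: {self.value!r}")


@dataclass(frozen=True)
class FragmentIdentifier:
    """A page-level pointer: a work identifier plus a 1-based page position."""

    base: Union[PersistentIdentifier, str]
    page_index: int

    def __post_init__(self):
        if self.page_index < 1:
            raise MalformedIdentifierError("page_index must be >= 1")

    def __str__(self) -> str:
        base = self.base.value if isinstance(self.base, PersistentIdentifier) else self.base
        return f"{base}#page={self.page_index}"


_LSID_RE = re.compile(r"^urn:lsid:", re.IGNORECASE)


def parse_lsid(text: str) -> LSID:
    """Parse an LSID string into its structured parts.

    Raises :class:`MalformedIdentifierError` unless the string has the
    ``urn:lsid:`` scheme followed by at least authority, namespace and
    object id.
    """
    if not text:
        raise MalformedIdentifierError("empty LSID string")
    text = text.strip()
    if not _LSID_RE.match(text):
        raise MalformedIdentifierError(f"not an LSID (missing urn:lsid: prefix): {text!r}")
    rest = text[len("urn:lsid:"):]
    parts = rest.split(":")
    if len(parts) < 3 or any(p == "" for p in parts[:3]):
        raise MalformedIdentifierError(f"LSID needs authority:namespace:object: {text!r}")
    if len(parts) > 4:
        raise MalformedIdentifierError(f"too many components in LSID: {text!r}")
    revision = parts[3] if len(parts) == 4 else None
    return LSID(parts[0], parts[1], parts[2], revision)


_DOI_PREFIXES = ("https://doi.org/", "http://doi.org/", "https://dx.doi.org/",
                 "http://dx.doi.org/", "doi.org/", "doi:")
_DOI_RE = re.compile(r"^10\.\d{2,9}(\.\d+)*/\S+$")


def normalize_doi(text: str) -> PersistentIdentifier:
    """Strip resolver prefixes and case-fold a DOI.

    DOIs compare case-insensitively, so the canonical value is lower-cased;
    the original casing (minus the prefix) is kept for display.  Idempotent.
    """
    if not text:
        raise MalformedIdentifierError("empty DOI string")
    residue = text.strip()
    lowered = residue.lower()
    for prefix in _DOI_PREFIXES:
        if lowered.startswith(prefix):
            residue = residue[len(prefix):]
            break
    if not _DOI_RE.match(residue.lower()):
        raise MalformedIdentifierError(f"not a DOI: {text!r}")
    return PersistentIdentifier(IdKind.DOI, residue.lower(), display=residue)


def classify_url(url: str) -> PersistentIdentifier:
    """Type a bare link: a URL whose path ends ``.pdf`` (case-insensitive)
    is classed as a PDF link, anything else as URL.

    The split between the two kinds is a working convention (source
    databases do not record it); it is documented as such.
    """
    kind = IdKind.PDF if url.lower().split("?")[0].rstrip("/").endswith(".pdf") else IdKind.URL
    return PersistentIdentifier(kind, url.strip())


# Index Fungorum and MycoBank assign the same integer object id to the same
# nomenclatural record, so their LSIDs are interchangeable.
DEFAULT_EQUIVALENCE_RULES: tuple[frozenset, ...] = (
    frozenset({("indexfungorum.org", "names"), ("mycobank.org", "names")}),
)


def lsids_equivalent(a: LSID, b: LSID,
                     rules: Iterable[frozenset] = DEFAULT_EQUIVALENCE_RULES) -> bool:
    """True iff two LSIDs denote the same object.

    Either they are identical, or their (authority, namespace) pairs are
    declared interchangeable by a rule and the object ids are equal.
    Unknown authorities simply compare non-equivalent.
    """
    if a == b:
        return True
    if a.object_id != b.object_id:
        return False
    ka, kb = (a.authority, a.namespace), (b.authority, b.namespace)
    return any(ka in rule and kb in rule for rule in rules)


#: Work-level identifier preference, most citable first.  The Wikidata QID
#: is carried as a parallel identifier rather than a competitor, so it
#: ranks last: it is only "preferred" when nothing else exists.
DEFAULT_PRECEDENCE: tuple[IdKind, ...] = (
    IdKind.DOI, IdKind.HANDLE, IdKind.JSTOR, IdKind.BIOSTOR,
    IdKind.BHL, IdKind.URL, IdKind.PDF, IdKind.WIKIDATA,
)


def preferred_identifier(ids: Iterable[PersistentIdentifier],
                         precedence: Sequence[IdKind] = DEFAULT_PRECEDENCE,
                         ) -> PersistentIdentifier:
    """Pick the most citable identifier from a set.

    Deterministic: the first kind in ``precedence`` wins; ties within a
    kind break lexicographically on the canonical value, so the result is
    invariant under permutation of the input.
    """
    pool = list(ids)
    if not pool:
        raise EmptySetError("no identifiers to choose from")
    rank: Mapping[IdKind, int] = {k: i for i, k in enumerate(precedence)}
    return min(pool, key=lambda pid: (rank.get(pid.kind, len(rank)), pid.value))
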