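"""A small names/publications/people knowledge graph in RDF.

Names with DOI-bearing publications are exported as N-Triples using
schema.org terms (the TaxonName type follows the Bioschemas draft):
the LSID, in ``urn:lsid:`` form, is linked to the publication's DOI IRI
with ``schema:isBasedOn``.  ORCID-style person records — often messy,
user-supplied data — are cleaned, then emitted as person/affiliation/
authorship triples.  The assembled graph answers joins like "authors
affiliated with organisation X who published a name", the canonical
demonstration query.

All vocabulary IRIs live in one table (:data:`VOCAB`) so the choice of
predicates is swappable in one place.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF

from .citation_model import NameRecord, Work
from .errors import NoDoiError, PersonRejected
from .identifiers import IdKind

__all__ = [
    "VOCAB",
    "PersonRecord",
    "name_to_triples",
    "clean_person_record",
    "person_to_triples",
    "triples_to_ntriples",
    "assemble_graph",
    "query_org_authors",
    "repair_url",
]

SCHEMA = Namespace("https://schema.org/")

#: Vocabulary constants — change here to retarget the graph.
VOCAB = {
    "TaxonName": SCHEMA.TaxonName,
    "Person": SCHEMA.Person,
    "Organization": SCHEMA.Organization,
    "name": SCHEMA.name,
    "isBasedOn": SCHEMA.isBasedOn,
    "affiliation": SCHEMA.affiliation,
    "creator": SCHEMA.creator,
}

Triple = Tuple[URIRef, URIRef, object]


@dataclass
class PersonRecord:
    """A cleaned author record in the shape of an ORCID export."""

    orcid: str  # full https://orcid.org/... IRI
    given: str = ""
    family: str = ""
    affiliations: Sequence[tuple[str, str, str]] = field(default_factory=tuple)
    #: (organisation name, id scheme e.g. RINGGOLD, id value)
    work_dois: Sequence[str] = field(default_factory=tuple)  # bare 10.x/... DOIs

    @property
    def display_name(self) -> str:
        return " ".join(p for p in (self.given, self.family) if p)


def doi_iri(doi_value: str) -> URIRef:
    return URIRef(f"https://doi.org/{doi_value}")


def org_iri(scheme: str, value: str) -> URIRef:
    """Deterministic organisation node: urn:org:{scheme}:{value}."""
    return URIRef(f"urn:org:{scheme}:{value}")


def name_to_triples(name: NameRecord, work: Work) -> list[Triple]:
    """Three triples per DOI-bearing name: type, name literal, isBasedOn.

    Raises :class:`NoDoiError` when the work lacks a DOI — only names
    whose publication has a DOI belong in the graph, and the caller is
    expected to filter.
    """
    dois = sorted(p.value for p in work.identifiers if p.kind is IdKind.DOI)
    if not dois:
        raise NoDoiError(f"work {work.work_id} has no DOI")
    subject = URIRef(str(name.lsid))
    return [
        (subject, RDF.type, VOCAB["TaxonName"]),
        (subject, VOCAB["name"], Literal(name.name_string)),
        (subject, VOCAB["isBasedOn"], doi_iri(dois[0])),
    ]


_ORCID_IRI_RE = re.compile(r"^https://orcid\.org/(\d{4}-){3}\d{3}[\dX]$")
_CONTROL_RE = re.compile(r"[\x00-\x1f\x7f]")


def repair_url(text: str) -> Optional[str]:
    """Best-effort repair of a user-supplied URL.

    Strips whitespace/control characters and supplies a missing https
    scheme for known hosts (orcid.org, doi.org).  Returns None when the
    residue still is not an absolute http(s) IRI.
    """
    if text is None:
        return None
    cleaned = _CONTROL_RE.sub("", str(text)).strip()
    if not cleaned:
        return None
    if re.match(r"^(orcid\.org|doi\.org|dx\.doi\.org|www\.)", cleaned, re.IGNORECASE):
        cleaned = "https://" + cleaned
    if not re.match(r"^https?://\S+$", cleaned):
        return None
    return cleaned


def clean_person_record(raw: dict) -> PersonRecord:
    """Normalize a loosely structured person record.

    Fields that cannot be repaired into valid IRIs are dropped; the
    record as a whole is rejected (:class:`PersonRejected`) only when the
    ORCID itself is unrecoverable or nothing at all remains.
    """
    if not raw:
        raise PersonRejected("empty-record")
    orcid = repair_url(raw.get("orcid") or raw.get("@id") or "")
    if orcid is None or not _ORCID_IRI_RE.match(orcid):
        raise PersonRejected("bad-orcid", str(raw.get("orcid")))
    given = str(raw.get("given") or raw.get("givenName") or "").strip()
    family = str(raw.get("family") or raw.get("familyName") or "").strip()
    affiliations = []
    for aff in raw.get("affiliations", []):
        org_name = str(aff.get("name") or "").strip()
        scheme = str(aff.get("scheme") or "").strip()
        value = str(aff.get("value") or "").strip()
        if scheme and not value:
            continue  # invariant: a scheme needs a value
        if not (org_name or (scheme and value)):
            continue
        affiliations.append((org_name, scheme, value))
    dois = []
    for w in raw.get("works", []):
        url = repair_url(w if isinstance(w, str) else w.get("doi", ""))
        if url is None:
            continue
        m = re.match(r"^https?://(dx\.)?doi\.org/(?P<doi>10\..+)$", url)
        if m:
            dois.append(m.group("doi").rstrip("/"))
    return PersonRecord(orcid=orcid, given=given, family=family,
                        affiliations=tuple(affiliations), work_dois=tuple(dois))


def person_to_triples(p: PersonRecord) -> list[Triple]:
    """Type + name literal + one affiliation triple per organisation + one
    authorship triple (work → creator → person) per work DOI.

    Two people sharing an organisation produce the same organisation IRI,
    which is what makes the affiliation join work.
    """
    subject = URIRef(p.orcid)
    triples: list[Triple] = [
        (subject, RDF.type, VOCAB["Person"]),
        (subject, VOCAB["name"], Literal(p.display_name or p.orcid)),
    ]
    for org_name, scheme, value in p.affiliations:
        node = org_iri(scheme, value) if scheme else org_iri("name", re.sub(r"\W+", "-", org_name))
        triples.append((subject, VOCAB["affiliation"], node))
    for doi in p.work_dois:
        triples.append((doi_iri(doi), VOCAB["creator"], subject))
    return triples


def triples_to_ntriples(triples: Iterable[Triple], path) -> int:
    """Serialize triples to an N-Triples file; returns the distinct-triple
    count written."""
    g = Graph()
    for t in triples:
        g.add(t)
    g.serialize(destination=str(path), format="nt", encoding="utf-8")
    return len(g)


def assemble_graph(paths: Iterable) -> Graph:
    """Union N-Triples files into one graph (set semantics: duplicates
    across files collapse)."""
    g = Graph()
    for path in paths:
        g.parse(str(path), format="nt")
    return g


def query_org_authors(g: Graph, org_scheme: str, org_value: str,
                      lsid_authority: Optional[str] = None) -> set[tuple[str, str]]:
    """Authors affiliated with an organisation who published a taxon name.

    The join name → publication → person → organisation, optionally
    restricted to names from one LSID authority.  Returns (person IRI,
    display name) pairs; empty set when nothing joins.
    """
    org = org_iri(org_scheme, org_value)
    authority_filter = ""
    if lsid_authority:
        prefix = f"urn:lsid:{lsid_authority.lower()}:"
        authority_filter = f'FILTER STRSTARTS(STR(?taxonName), "{prefix}")'
    query = """
        SELECT DISTINCT ?person ?personName WHERE {
            ?taxonName a <%(TaxonName)s> ;
                       <%(isBasedOn)s> ?work .
            ?work <%(creator)s> ?person .
            ?person <%(affiliation)s> ?org ;
                    <%(name)s> ?personName .
            %(filter)s
        }
    """ % {**{k: str(v) for k, v in VOCAB.items()}, "filter": authority_filter}
    return {(str(row.person), str(row.personName))
            for row in g.query(query, initBindings={"org": org})}
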