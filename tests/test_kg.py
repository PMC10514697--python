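"""RDF export and the names/publications/people graph."""

import itertools

import pytest
from rdflib import URIRef

from taxolink.citation_model import MicroCitation, NameRecord, Work
from taxolink.errors import NoDoiError, PersonRejected
from taxolink.identifiers import IdKind, LSID, PersistentIdentifier
from taxolink.kg import (PersonRecord, VOCAB, assemble_graph,
                         clean_person_record, name_to_triples, org_iri,
                         person_to_triples, query_org_authors, repair_url,
                         triples_to_ntriples)


def make_name(n="839249", name="Cordyceps changchunensis"):
    return NameRecord(
        lsid=LSID("indexfungorum.org", "names", n), name_string=name,
        microcitation=MicroCitation(raw="x", container="MycoKeys"))


def make_work(doi="10.3897/mycokeys.83.72325", work_id="w1"):
    ids = frozenset({PersistentIdentifier(IdKind.DOI, doi)}) if doi else frozenset()
    return Work(work_id=work_id, container="MycoKeys", identifiers=ids)


class TestNameToTriples:
    def test_lsid_linked_to_doi_via_isBasedOn(self):
        triples = name_to_triples(make_name(), make_work())
        assert len(triples) == 3
        subject = URIRef("urn:lsid:indexfungorum.org:names:839249")
        assert (subject, VOCAB["isBasedOn"],
                URIRef("https://doi.org/10.3897/mycokeys.83.72325")) in triples
        assert any(p == VOCAB["name"] for _, p, _ in triples)

    def test_no_doi_errors(self):
        with pytest.raises(NoDoiError):
            name_to_triples(make_name(), make_work(doi=None))

    def test_three_triples_per_name_batch(self):
        triples = []
        for i in range(17):
            triples.extend(name_to_triples(
                make_name(str(i), f"Genus sp{i}"),
                make_work(f"10.1/x{i}", f"w{i}")))
        assert len(triples) == 3 * 17


class TestCleanPersonRecord:
    def test_whitespace_and_scheme_repair(self):
        rec = clean_person_record({
            "orcid": " orcid.org/0000-0002-7101-9767\n",
            "given": "Rod", "family": "Page",
            "works": ["doi.org/10.1/abc "]})
        assert rec.orcid == "https://orcid.org/0000-0002-7101-9767"
        assert rec.work_dois == ("10.1/abc",)

    def test_url_repair_variants(self):
        assert repair_url("doi.org/10.1/abc ") == "https://doi.org/10.1/abc"
        assert repair_url("https://ok.example/x\n") == "https://ok.example/x"
        assert repair_url("not a url") is None

    def test_bad_orcid_rejected(self):
        with pytest.raises(PersonRejected) as exc:
            clean_person_record({"orcid": "not-an-id"})
        assert exc.value.reason == "bad-orcid"

    def test_empty_record_rejected(self):
        with pytest.raises(PersonRejected) as exc:
            clean_person_record({})
        assert exc.value.reason == "empty-record"

    def test_invalid_work_fields_dropped_not_fatal(self):
        rec = clean_person_record({
            "orcid": "https://orcid.org/0000-0002-7101-9767",
            "works": ["%%%garbage%%%", "https://doi.org/10.5/ok"]})
        assert rec.work_dois == ("10.5/ok",)


class TestPersonToTriples:
    def person(self, orcid="https://orcid.org/0000-0002-7101-9767"):
        return PersonRecord(orcid=orcid, given="Ana", family="Kirk",
                            affiliations=(("RBG Example", "RINGGOLD", "41803"),),
                            work_dois=("10.1/a", "10.2/b"))

    def test_triple_count_structure(self):
        triples = person_to_triples(self.person())
        # type + name + 1 affiliation + 2 authorship
        assert len(triples) == 5

    def test_minimal_person_type_and_name_only(self):
        p = PersonRecord(orcid="https://orcid.org/0000-0002-7101-9767",
                         given="Bo", family="Li")
        assert len(person_to_triples(p)) == 2

    def test_shared_organisation_same_iri(self):
        p1 = self.person()
        p2 = PersonRecord(orcid="https://orcid.org/0000-0001-0000-0001",
                          given="Bo", family="Li",
                          affiliations=(("RBG Example", "RINGGOLD", "41803"),))
        orgs1 = {o for _, p, o in person_to_triples(p1) if p == VOCAB["affiliation"]}
        orgs2 = {o for _, p, o in person_to_triples(p2) if p == VOCAB["affiliation"]}
        assert orgs1 == orgs2 == {org_iri("RINGGOLD", "41803")}


class TestAssembleGraph:
    def test_set_union_across_files(self, tmp_path):
        t1 = name_to_triples(make_name("1"), make_work("10.1/a", "w1"))
        t2 = name_to_triples(make_name("2"), make_work("10.1/b", "w2"))
        # share one duplicate triple across files: sizes 3 and 4 -> graph of 6
        triples_to_ntriples(t1, tmp_path / "a.nt")
        triples_to_ntriples(t2 + [t1[0]], tmp_path / "b.nt")
        g = assemble_graph([tmp_path / "a.nt", tmp_path / "b.nt"])
        assert len(g) == 6

    def test_empty_file(self, tmp_path):
        (tmp_path / "e.nt").write_text("")
        assert len(assemble_graph([tmp_path / "e.nt"])) == 0

    def test_malformed_line_raises(self, tmp_path):
        (tmp_path / "bad.nt").write_text("<urn:x> not ntriples\n")
        with pytest.raises(Exception):
            assemble_graph([tmp_path / "bad.nt"])

    def test_round_trip_count(self, tmp_path):
        triples = list(itertools.chain.from_iterable(
            name_to_triples(make_name(str(i)), make_work(f"10.1/{i}", f"w{i}"))
            for i in range(9)))
        n = triples_to_ntriples(triples, tmp_path / "x.nt")
        assert n == len(assemble_graph([tmp_path / "x.nt"])) == 27


def build_demo_graph(tmp_path):
    """name isBasedOn doi; person authored doi; person affiliated org."""
    name = NameRecord(lsid=LSID("ipni.org", "names", "77103635-1"),
                      name_string="Planta exempla",
                      microcitation=MicroCitation(raw="x", container="Taxon"))
    work = make_work("10.5/plant", "w1")
    person = PersonRecord(orcid="https://orcid.org/0000-0002-7101-9767",
                          given="Ana", family="Kirk",
                          affiliations=(("RBG Example", "RINGGOLD", "41803"),),
                          work_dois=("10.5/plant",))
    bystander = PersonRecord(orcid="https://orcid.org/0000-0001-0000-0001",
                             given="Bo", family="Li",
                             affiliations=(("Elsewhere", "RINGGOLD", "99999"),),
                             work_dois=("10.5/plant",))
    triples_to_ntriples(name_to_triples(name, work), tmp_path / "names.nt")
    triples_to_ntriples(person_to_triples(person) + person_to_triples(bystander),
                        tmp_path / "persons.nt")
    return assemble_graph([tmp_path / "names.nt", tmp_path / "persons.nt"])


class TestQueryOrgAuthors:
    def test_hand_traced_join(self, tmp_path):
        g = build_demo_graph(tmp_path)
        hits = query_org_authors(g, "RINGGOLD", "41803")
        assert hits == {("https://orcid.org/0000-0002-7101-9767", "Ana Kirk")}

    def test_other_org_empty(self, tmp_path):
        g = build_demo_graph(tmp_path)
        assert query_org_authors(g, "RINGGOLD", "12345") == set()

    def test_authority_filter(self, tmp_path):
        g = build_demo_graph(tmp_path)
        assert query_org_authors(g, "RINGGOLD", "41803", "ipni.org") \
            == {("https://orcid.org/0000-0002-7101-9767", "Ana Kirk")}
        assert query_org_authors(g, "RINGGOLD", "41803", "ion.org") == set()

    def test_matches_brute_force_join(self, tmp_path):
        g = build_demo_graph(tmp_path)
        from rdflib import RDF
        expected = set()
        for name_node in g.subjects(RDF.type, VOCAB["TaxonName"]):
            for work in g.objects(name_node, VOCAB["isBasedOn"]):
                for person in g.objects(work, VOCAB["creator"]):
                    if (person, VOCAB["affiliation"],
                            org_iri("RINGGOLD", "41803")) in g:
                        for label in g.objects(person, VOCAB["name"]):
                            expected.add((str(person), str(label)))
        assert query_org_authors(g, "RINGGOLD", "41803") == expected
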