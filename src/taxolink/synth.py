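"""Synthetic name databases with known ground truth.

Harvesting real nomenclator dumps is out of reach for tests, so this
module fabricates the same shapes: journals with volumes of articles
holding contiguous page ranges, taxonomic names whose microcitations are
rendered from their true works, ORCID-style person records, and a
corruption model reproducing the error archetypes seen in real source
databases (wrong journal, perturbed volume, impossible page, drifted
year).  Every corpus is reproducible from a single integer seed.

Design points that matter for matching behaviour:

* journals are assigned distinct publication eras (stratified start
  years), so the year window can discriminate between venues that share
  volume numbers — mirroring the fact that real journals with the same
  volume count rarely publish the same years;
* a configurable fraction of journals uses continuous article numbering:
  every article starts on page 1 and carries its article number as the
  DOI tail, making page containment meaningless there;
* microcitations are rendered in the terse nomenclator house style
  (no author block): ``<container> <volume>: <page> (<year>)`` or
  ``<container>, volume <v>, issue no. <n>``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .citation_model import AliasTable, MicroCitation, NameRecord, SourceDb, Work
from .errors import InvalidSpecError
from .identifiers import IdKind, LSID, PersistentIdentifier

__all__ = ["CorpusSpec", "Corpus", "generate_corpus", "corrupt_corpus",
           "render_microcitation"]

_GENUS_SYLLABLES = ["cor", "dy", "ceps", "my", "co", "phila", "fun", "gus",
                    "lep", "io", "ta", "rus", "sella", "phora", "derma"]
_SURNAMES = ["Hu", "Dai", "Zhao", "Guo", "Tuo", "Rao", "Qi", "Zhang", "Li",
             "Smith", "Jones", "Kirk", "Persoon", "Fries", "Saccardo"]
_JOURNAL_WORDS = ["Acta", "Annales", "Journal", "Bulletin", "Mycologia",
                  "Fungorum", "Plantarum", "Taxonomica", "Exempla", "Novitates",
                  "Systematica", "Botanica"]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus; the seed fully determines output."""

    n_journals: int = 10
    volumes_per_journal: int = 3
    articles_per_volume: int = 8
    names_per_article: int = 2
    continuous_numbering_fraction: float = 0.2
    doi_fraction: float = 0.8
    qid_fraction: float = 0.3
    corruption_rates: dict = field(default_factory=dict)
    n_persons: int = 6
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_journals", "volumes_per_journal", "articles_per_volume",
                  "names_per_article"):
            if getattr(self, f) < 1:
                raise InvalidSpecError(f"{f} must be >= 1")
        fracs = {"continuous_numbering_fraction": self.continuous_numbering_fraction,
                 "doi_fraction": self.doi_fraction, "qid_fraction": self.qid_fraction,
                 **{f"corruption_rates[{k}]": v for k, v in self.corruption_rates.items()}}
        for label, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidSpecError(f"{label} must be in [0, 1]")
        unknown = set(self.corruption_rates) - {"wrong_journal", "wrong_volume",
                                                "page_offset", "year_offset"}
        if unknown:
            raise InvalidSpecError(f"unknown corruption kinds: {sorted(unknown)}")


@dataclass
class Corpus:
    names: list[NameRecord]
    works: list[Work]
    persons: list[dict]
    ground_truth: dict  # str(lsid) -> work_id
    aliases: AliasTable
    spec: CorpusSpec


def render_microcitation(mc: MicroCitation) -> str:
    """Render a microcitation in the nomenclator house style."""
    if mc.article_number is not None:
        return f"{mc.container}, volume {mc.volume}, issue no. {mc.article_number}"
    s = f"{mc.container} {mc.volume}: {mc.page}"
    if mc.year is not None:
        s += f" ({mc.year})"
    if mc.authors:
        s = f"{mc.authors}, {s}"
    return s


def _journal_name(rng: random.Random, index: int) -> str:
    words = rng.sample(_JOURNAL_WORDS, 2)
    return f"{words[0]} {words[1]} {index + 1}"


def _abbreviate(name: str) -> str:
    parts = name.split()
    return " ".join(p if p.isdigit() else p[:4] + "." for p in parts)


def _species_name(rng: random.Random) -> str:
    genus = "".join(rng.sample(_GENUS_SYLLABLES, 3)).capitalize()
    epithet = "".join(rng.sample(_GENUS_SYLLABLES, 2))
    return f"{genus} {epithet}"


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Build names, works, persons and the true LSID→work mapping.

    Within each regular volume, page ranges are contiguous and
    non-overlapping, starting from page 1; continuous-numbering journals
    instead start every article on page 1 and always mint a DOI whose
    tail is the article number.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    n_continuous = round(spec.continuous_numbering_fraction * spec.n_journals)
    era_span = max(1, (2015 - 1750) // spec.n_journals)

    aliases = AliasTable()
    works: list[Work] = []
    names: list[NameRecord] = []
    ground_truth: dict[str, str] = {}
    artnum_counter = 700000
    qid_counter = 90000000
    lsid_serial = 800000
    sources = [SourceDb.INDEX_FUNGORUM, SourceDb.IPNI, SourceDb.ION]

    for j in range(spec.n_journals):
        container = _journal_name(rng, j)
        aliases.add(_abbreviate(container), container)
        continuous = j < n_continuous
        # distinct eras: journals sharing volume numbers publish in
        # different years, so the year window can tell them apart
        start_year = 1750 + j * era_span + rng.randint(0, max(1, era_span - spec.volumes_per_journal - 3))
        for v in range(1, spec.volumes_per_journal + 1):
            year = start_year + v - 1
            page_cursor = 1
            for a in range(spec.articles_per_volume):
                length = rng.randint(4, 20)
                work_id = f"w{j:02d}v{v}a{a:02d}"
                ids = set()
                artnum = None
                if continuous:
                    page_start, page_end = 1, length
                    artnum_counter += 1
                    artnum = str(artnum_counter)
                    ids.add(PersistentIdentifier(
                        IdKind.DOI, f"10.9999/synj{j:02d}.{year}.{artnum}"))
                else:
                    page_start, page_end = page_cursor, page_cursor + length - 1
                    page_cursor += length
                    if rng.random() < spec.doi_fraction:
                        ids.add(PersistentIdentifier(
                            IdKind.DOI, f"10.9999/reg{j:02d}.{v}.{page_start}"))
                if rng.random() < spec.qid_fraction:
                    qid_counter += 1
                    ids.add(PersistentIdentifier(IdKind.WIKIDATA, f"Q{qid_counter}"))
                authors = tuple(rng.sample(_SURNAMES, rng.randint(1, 3)))
                works.append(Work(
                    work_id=work_id, container=container, volume=str(v),
                    page_start=page_start, page_end=page_end, year=year,
                    title=f"On {_species_name(rng)}", authors=authors,
                    identifiers=frozenset(ids), article_number=artnum))
                for _ in range(spec.names_per_article):
                    lsid_serial += 1
                    lsid = LSID("example.org", "names", str(lsid_serial))
                    if continuous:
                        mc = MicroCitation(raw="", container=container,
                                           volume=str(v), article_number=artnum)
                    else:
                        mc = MicroCitation(raw="", container=container,
                                           volume=str(v),
                                           page=rng.randint(page_start, page_end),
                                           year=year)
                    mc = replace(mc, raw=render_microcitation(mc))
                    names.append(NameRecord(
                        lsid=lsid, name_string=_species_name(rng), rank="sp.",
                        microcitation=mc,
                        source_db=sources[(lsid_serial) % len(sources)]))
                    ground_truth[str(lsid)] = work_id

    persons = _generate_persons(rng, spec, works)
    return Corpus(names=names, works=works, persons=persons,
                  ground_truth=ground_truth, aliases=aliases, spec=spec)


_ORGS = [("Royal Botanic Gardens Example", "RINGGOLD", "41803"),
         ("Institute for Synthetic Mycology", "RINGGOLD", "12345"),
         ("Example Natural History Museum", "GRID", "grid.0001.1")]


def _generate_persons(rng: random.Random, spec: CorpusSpec,
                      works: Sequence[Work]) -> list[dict]:
    """Raw JSON-LD-like person records, deliberately a little messy
    (missing schemes, stray whitespace) so the cleaning step has work."""
    doi_works = [w for w in works
                 if any(p.kind is IdKind.DOI for p in w.identifiers)]
    persons = []
    for i in range(spec.n_persons):
        digits = f"{rng.randint(0, 9999):04d}-{rng.randint(0, 9999):04d}-{i:04d}-{rng.randint(0, 999):03d}{rng.choice('0123456789X')}"
        orcid = f"https://orcid.org/{digits[:19]}"
        if rng.random() < 0.3:
            orcid = f" orcid.org/{digits[:19]}\n"  # messy, repairable
        n_works = rng.randint(1, min(3, len(doi_works))) if doi_works else 0
        chosen = rng.sample(doi_works, n_works) if n_works else []
        dois = []
        for w in chosen:
            doi = sorted(p.value for p in w.identifiers if p.kind is IdKind.DOI)[0]
            dois.append(f"doi.org/{doi} " if rng.random() < 0.3 else doi and f"https://doi.org/{doi}")
        org = _ORGS[i % len(_ORGS)]
        persons.append({
            "orcid": orcid,
            "given": rng.choice(["Ana", "Bo", "Chen", "Dana", "Eli", "Fen"]),
            "family": rng.choice(_SURNAMES),
            "affiliations": [{"name": org[0], "scheme": org[1], "value": org[2]}],
            "works": dois,
        })
    return persons


_CORRUPTION_ORDER = ("wrong_journal", "wrong_volume", "page_offset", "year_offset")


def corrupt_corpus(names: Sequence[NameRecord], rates: dict, seed: int,
                   ) -> tuple[list[NameRecord], list[dict]]:
    """Apply independent per-name corruptions; return new records + a log.

    wrong_journal swaps the container for another venue in the corpus;
    wrong_volume perturbs the volume by ±1; page_offset pushes the page
    beyond any plausible range; year_offset drifts the year by ±2.  The
    raw string is re-rendered after editing so downstream parsing sees
    the corrupted citation.  The log records exactly what changed.
    """
    rng = random.Random(seed)
    containers = sorted({n.microcitation.container for n in names})
    out: list[NameRecord] = []
    log: list[dict] = []
    for record in names:
        mc = record.microcitation
        for kind in _CORRUPTION_ORDER:
            rate = rates.get(kind, 0.0)
            if rate <= 0.0 or rng.random() >= rate:
                continue
            if kind == "wrong_journal" and len(containers) > 1:
                others = [c for c in containers if c != mc.container]
                new = rng.choice(others)
                log.append({"lsid": str(record.lsid), "corruption": kind,
                            "old": mc.container, "new": new})
                mc = replace(mc, container=new)
            elif kind == "wrong_volume" and mc.volume and mc.volume.isdigit():
                new = str(max(1, int(mc.volume) + rng.choice((-1, 1))))
                log.append({"lsid": str(record.lsid), "corruption": kind,
                            "old": mc.volume, "new": new})
                mc = replace(mc, volume=new)
            elif kind == "page_offset" and mc.page is not None:
                new = mc.page + 10000
                log.append({"lsid": str(record.lsid), "corruption": kind,
                            "old": str(mc.page), "new": str(new)})
                mc = replace(mc, page=new)
            elif kind == "year_offset" and mc.year is not None:
                new = mc.year + rng.choice((-2, 2))
                log.append({"lsid": str(record.lsid), "corruption": kind,
                            "old": str(mc.year), "new": str(new)})
                mc = replace(mc, year=new)
        mc = replace(mc, raw=render_microcitation(mc))
        out.append(NameRecord(lsid=record.lsid, name_string=record.name_string,
                              microcitation=mc, rank=record.rank,
                              source_db=record.source_db))
    return out, log
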