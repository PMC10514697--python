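"""Tabular/JSON input and output for the linking pipeline.

Name records travel as a five-column TSV (lsid, name, rank,
citation_string, source); bibliographies as CSL-like JSON records (or the
equivalent TSV); person records as JSON Lines; mappings as TSV.  All
writers are deterministic (fixed ordering, LF endings).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .citation_model import (AliasTable, MicroCitation, NameRecord, SourceDb,
                             Work, parse_microcitation)
from .errors import ParseFailureError
from .identifiers import (IdKind, PersistentIdentifier, classify_url,
                          normalize_doi, parse_lsid)
from .match_engine import MappingEntry, Method
from .synth import Corpus

NAMES_COLUMNS = ["lsid", "name", "rank", "citation_string", "source"]
MAPPING_COLUMNS = ["lsid", "work_id", "method", "identifiers", "flags", "suggestion"]


def write_names_tsv(names: Sequence[NameRecord], path) -> None:
    rows = [{"lsid": str(n.lsid), "name": n.name_string, "rank": n.rank or "",
             "citation_string": n.microcitation.raw, "source": n.source_db.value}
            for n in names]
    pd.DataFrame(rows, columns=NAMES_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_names_tsv(path, aliases: Optional[AliasTable] = None,
                   ) -> tuple[list[NameRecord], list[dict]]:
    """Parse a names table; rows whose citation string cannot be parsed are
    returned separately as failures, not silently dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records, failures = [], []
    for _, row in df.iterrows():
        try:
            mc = parse_microcitation(row["citation_string"], aliases)
        except ParseFailureError as exc:
            failures.append({"lsid": row["lsid"], "reason": str(exc)})
            continue
        records.append(NameRecord(
            lsid=parse_lsid(row["lsid"]), name_string=row["name"],
            rank=row["rank"] or None, microcitation=mc,
            source_db=SourceDb(row["source"]) if row["source"] else SourceDb.OTHER))
    return records, failures


def _work_to_csl(work: Work) -> dict:
    rec: dict = {"id": work.work_id, "container-title": work.container}
    if work.volume:
        rec["volume"] = work.volume
    if work.issue:
        rec["issue"] = work.issue
    if work.page_start is not None:
        rec["page"] = (str(work.page_start) if work.page_end in (None, work.page_start)
                       else f"{work.page_start}-{work.page_end}")
    if work.year is not None:
        rec["issued"] = {"date-parts": [[work.year]]}
    if work.title:
        rec["title"] = work.title
    if work.authors:
        rec["author"] = [{"family": a} for a in work.authors]
    if work.article_number:
        rec["article-number"] = work.article_number
    for pid in sorted(work.identifiers):
        if pid.kind is IdKind.DOI:
            rec["DOI"] = pid.display
        elif pid.kind is IdKind.WIKIDATA:
            rec["QID"] = pid.value
        elif pid.kind in (IdKind.URL, IdKind.PDF):
            rec.setdefault("URL", pid.value)
        else:
            rec.setdefault(pid.kind.value, pid.value)
    return rec


def _csl_to_work(rec: dict) -> Work:
    page_start = page_end = None
    page = str(rec.get("page", "") or "")
    if page:
        bits = page.replace("–", "-").split("-")
        page_start = int(bits[0])
        page_end = int(bits[-1]) if len(bits) > 1 else page_start
    year = None
    issued = rec.get("issued")
    if isinstance(issued, dict):
        parts = issued.get("date-parts") or [[None]]
        year = parts[0][0]
    elif issued is not None:
        year = int(issued)
    ids = set()
    if rec.get("DOI"):
        ids.add(normalize_doi(rec["DOI"]))
    if rec.get("QID"):
        ids.add(PersistentIdentifier(IdKind.WIKIDATA, rec["QID"]))
    if rec.get("URL"):
        ids.add(classify_url(rec["URL"]))
    for kind in (IdKind.HANDLE, IdKind.JSTOR, IdKind.BIOSTOR, IdKind.BHL):
        if rec.get(kind.value):
            ids.add(PersistentIdentifier(kind, rec[kind.value]))
    return Work(
        work_id=str(rec["id"]), container=rec.get("container-title", ""),
        volume=rec.get("volume"), issue=rec.get("issue"),
        page_start=page_start, page_end=page_end, year=year,
        title=rec.get("title"),
        authors=tuple(a.get("family", "") for a in rec.get("author", [])),
        identifiers=frozenset(ids), article_number=rec.get("article-number"))


def write_works_json(works: Sequence[Work], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([_work_to_csl(w) for w in works], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_works_json(path) -> list[Work]:
    with open(path, encoding="utf-8") as fh:
        return [_csl_to_work(rec) for rec in json.load(fh)]


def write_persons_jsonl(persons: Sequence[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in persons:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_persons_jsonl(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_alias_tsv(aliases: AliasTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for alias, canonical in sorted(aliases._map.items()):
            fh.write(f"{alias}\t{canonical}\n")


def write_mapping_tsv(entries: Sequence[MappingEntry], path) -> None:
    rows = []
    for e in sorted(entries, key=lambda e: str(e.lsid)):
        rows.append({
            "lsid": str(e.lsid), "work_id": e.work_id or "",
            "method": e.method.value,
            "identifiers": ";".join(sorted(f"{p.kind.value}:{p.value}"
                                           for p in e.identifiers)),
            "flags": ";".join(sorted(f.value for f in e.flags)),
            "suggestion": e.suggestion.work_id if e.suggestion else "",
        })
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_mapping_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_ground_truth_tsv(ground_truth: dict, path) -> None:
    pd.DataFrame(sorted(ground_truth.items()), columns=["lsid", "work_id"]) \
        .to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_corpus(corpus: Corpus, out_dir) -> dict:
    """Write a synthetic corpus in the formats the pipeline ingests;
    returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"names": out / "names.tsv", "works": out / "works.json",
             "persons": out / "persons.jsonl", "aliases": out / "aliases.tsv",
             "ground_truth": out / "ground_truth.tsv"}
    write_names_tsv(corpus.names, paths["names"])
    write_works_json(corpus.works, paths["works"])
    write_persons_jsonl(corpus.persons, paths["persons"])
    write_alias_tsv(corpus.aliases, paths["aliases"])
    write_ground_truth_tsv(corpus.ground_truth, paths["ground_truth"])
    return paths
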