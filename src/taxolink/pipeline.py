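"""End-to-end orchestration: parse → match → export → report.

``run_linking`` takes a config naming the input tables, resolves every
name's microcitation against the bibliography, and writes the mapping
TSV, a CoLDP-style package, an N-Triples export of DOI-bearing names and
a coverage report.  Every flagged record is surfaced in the run summary
and the flags report — links between databases attract scrutiny, so the
diagnostics are first-class output, not log noise.

``lookup_name`` answers the interactive question served by a name-lookup
web front end: given a name string, return its persistent identifiers
(most citable first) and a formatted citation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as tio
from .citation_model import AliasTable, NameRecord, Work, format_citation
from .coldp import write_coldp
from .coverage import (coverage_percentage, decade_container_matrix,
                       long_tail_curve, summarize_by_identifier)
from .errors import MissingFieldError, TaxolinkError
from .identifiers import DEFAULT_PRECEDENCE, IdKind
from .kg import clean_person_record, name_to_triples, person_to_triples, \
    triples_to_ntriples
from .match_engine import (DEFAULT_CONFIG, MappingEntry, MatchConfig, Method,
                           build_index, resolve)
from .errors import PersonRejected

log = logging.getLogger("taxolink")

__all__ = ["RunConfig", "run_linking", "lookup_name", "MappingStore"]


@dataclass
class RunConfig:
    """Paths and knobs for one linking run."""

    names_path: str
    works_path: str
    out_dir: str
    aliases_path: Optional[str] = None
    persons_path: Optional[str] = None
    match: MatchConfig = field(default_factory=MatchConfig)
    metadata: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        match = MatchConfig(**raw.pop("match", {}))
        cfg = cls(match=match, **raw)
        for p in (cfg.names_path, cfg.works_path, cfg.aliases_path, cfg.persons_path):
            if p is not None and not Path(p).exists():
                raise TaxolinkError(f"input path does not exist: {p}")
        return cfg


def _coverage_payload(entries, names) -> dict:
    counts = summarize_by_identifier(entries, names)
    payload = {"counts": {row: counts.loc[row].to_dict() for row in counts.index}}
    try:
        payload["coverage_percent"] = coverage_percentage(counts, precision=1)
    except ZeroDivisionError:
        payload["coverage_percent"] = None
    matched_lsids = {str(e.lsid) for e in entries if e.identifiers}
    df = pd.DataFrame([{
        "container": n.microcitation.container,
        "year": n.microcitation.year,
        "has_pid": str(n.lsid) in matched_lsids,
    } for n in names])
    if len(df):
        matrix, pid_pct = decade_container_matrix(df, top_k=50)
        payload["decade_matrix"] = {c: {str(k): int(v) for k, v in row.items()}
                                    for c, row in matrix.iterrows()}
        payload["pid_percentages"] = {k: (None if pd.isna(v) else v)
                                      for k, v in pid_pct.items()}
        payload["long_tail"] = long_tail_curve(df, top_n=100).to_dict("records")
    return payload


def run_linking(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a summary of counts and output paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aliases = AliasTable.from_tsv(cfg.aliases_path) if cfg.aliases_path else None
    works = tio.read_works_json(cfg.works_path)
    names, parse_failures = tio.read_names_tsv(cfg.names_path, aliases)
    index = build_index(works, aliases, cfg.match)
    works_by_id = {w.work_id: w for w in works}

    entries: list[MappingEntry] = []
    for record in names:
        entry = resolve(record.microcitation, index, lsid=record.lsid,
                        config=cfg.match)
        if entry.flags:
            log.warning("flagged lsid=%s flags=%s suggestion=%s", record.lsid,
                        ",".join(sorted(f.value for f in entry.flags)),
                        entry.suggestion.work_id if entry.suggestion else "-")
        entries.append(entry)

    mapping_path = out / "mapping.tsv"
    tio.write_mapping_tsv(entries, mapping_path)
    package = write_coldp(entries, names, works_by_id, out / "coldp",
                          metadata=cfg.metadata)

    nt_path = out / "names.nt"
    triples = []
    for record, entry in zip(names, entries):
        if entry.matched and any(p.kind is IdKind.DOI for p in entry.identifiers):
            triples.extend(name_to_triples(record, works_by_id[entry.work_id]))
    n_triples = triples_to_ntriples(triples, nt_path)

    persons_nt = None
    rejected_persons = 0
    if cfg.persons_path:
        ptriples = []
        for raw in tio.read_persons_jsonl(cfg.persons_path):
            try:
                ptriples.extend(person_to_triples(clean_person_record(raw)))
            except PersonRejected as exc:
                rejected_persons += 1
                log.warning("person rejected: %s", exc)
        persons_nt = out / "persons.nt"
        triples_to_ntriples(ptriples, persons_nt)

    coverage = _coverage_payload(entries, names)
    with open(out / "coverage.json", "w", encoding="utf-8") as fh:
        json.dump(coverage, fh, indent=1, sort_keys=True, default=str)

    methods = {m.value: sum(1 for e in entries if e.method is m) for m in Method}
    summary = {
        "total_names": len(names) + len(parse_failures),
        "parse_failures": len(parse_failures),
        "matched": sum(1 for e in entries if e.matched),
        "unmatched": methods[Method.UNMATCHED.value],
        "flagged": sum(1 for e in entries if e.flags),
        "by_method": methods,
        "rejected_persons": rejected_persons,
        "outputs": {"mapping": str(mapping_path), "coldp": str(out / "coldp"),
                    "names_nt": str(nt_path),
                    "persons_nt": str(persons_nt) if persons_nt else None,
                    "coverage": str(out / "coverage.json")},
        "name_triples": n_triples,
    }
    return summary


def _norm_name(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip().lower()


class MappingStore:
    """In-memory store backing the name-lookup service."""

    def __init__(self, names: Sequence[NameRecord], entries: Sequence[MappingEntry],
                 works_by_id: dict):
        self._by_name: dict[str, list] = {}
        by_lsid = {str(e.lsid): e for e in entries}
        for record in names:
            entry = by_lsid.get(str(record.lsid))
            if entry is None or not entry.matched:
                continue
            self._by_name.setdefault(_norm_name(record.name_string), []).append(
                (record, entry, works_by_id.get(entry.work_id)))

    def lookup(self, query: str):
        return self._by_name.get(_norm_name(query), [])


def lookup_name(query: str, store: MappingStore) -> list[dict]:
    """Exact-match lookup (case-insensitive, whitespace-normalized).

    Returns one hit per matching record — homonyms yield several — each
    with identifiers ordered by citability precedence and a formatted
    citation.  Empty list signals not-found.
    """
    rank = {k: i for i, k in enumerate(DEFAULT_PRECEDENCE)}
    hits = []
    for record, entry, work in store.lookup(query):
        ids = sorted(entry.identifiers,
                     key=lambda p: (rank.get(p.kind, len(rank)), p.value))
        try:
            citation = format_citation(work) if work else ""
        except MissingFieldError:
            citation = ""
        hits.append({"lsid": str(record.lsid), "name": record.name_string,
                     "identifiers": [f"{p.kind.value}:{p.display}" for p in ids],
                     "citation": citation})
    return hits
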