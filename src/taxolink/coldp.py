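"""Write and read the name→literature mapping as a CoLDP-style package.

The Catalogue of Life Data Package (CoLDP) is a delimited-text exchange
format for checklists.  Here it carries exactly the name↔reference
mapping: a names table (LSID, scientific name, rank, referenceID, page)
and a references table (referenceID, citation, DOI, link, remarks), plus
a small metadata file.  Reference identifiers follow the rule: a Wikidata
QID when the work has one, otherwise an id derived from its best
persistent identifier.

Tables are TSV, UTF-8, LF line endings, with fixed row ordering (names by
LSID, references by id) so identical inputs give byte-identical output.
Only names mapped to a work appear in the package; unmatched names go to
a sidecar ``unmapped.tsv`` for audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .citation_model import NameRecord, Work, format_citation
from .errors import (DanglingWorkError, MissingFieldError, NoIdentifierError,
                     ReferentialIntegrityError)
from .identifiers import IdKind, PersistentIdentifier, preferred_identifier
from .match_engine import MappingEntry

__all__ = ["ColdpPackage", "assign_reference_id", "write_coldp", "read_coldp"]

NAMES_FILE = "names.tsv"
REFERENCES_FILE = "references.tsv"
METADATA_FILE = "metadata.yaml"
UNMAPPED_FILE = "unmapped.tsv"

NAME_COLUMNS = ["ID", "scientificName", "rank", "referenceID", "page"]
REFERENCE_COLUMNS = ["ID", "citation", "DOI", "link", "remarks"]


@dataclass
class ColdpPackage:
    names_table: pd.DataFrame
    references_table: pd.DataFrame
    metadata: dict


def _sanitize(value: str) -> str:
    return re.sub(r"[^A-Za-z0-9-]", "-", value.replace("/", "-").replace(".", "-"))


def assign_reference_id(work: Work) -> str:
    """Derive the unique reference identifier for a work.

    A Wikidata QID serves directly; otherwise the id is built from the
    preferred persistent identifier, e.g. a DOI ``10.3897/mycokeys.83.72325``
    becomes ``doi-10-3897-mycokeys-83-72325``.  Deterministic, and
    injective as long as distinct works carry distinct identifiers.
    """
    if not work.identifiers:
        raise NoIdentifierError(f"work {work.work_id} has no identifiers")
    for pid in sorted(work.identifiers):
        if pid.kind is IdKind.WIKIDATA:
            return pid.value
    best = preferred_identifier(work.identifiers)
    return f"{best.kind.value.lower()}-{_sanitize(best.value)}"


def _doi_of(identifiers) -> str:
    dois = sorted(p.value for p in identifiers if p.kind is IdKind.DOI)
    return dois[0] if dois else ""

def _link_of(identifiers) -> str:
    non_doi = [p for p in identifiers
               if p.kind not in (IdKind.DOI, IdKind.WIKIDATA)]
    if not non_doi:
        return ""
    return preferred_identifier(non_doi).value


def _citation_of(work: Work) -> str:
    try:
        return format_citation(work)
    except MissingFieldError:
        # degenerate metadata: fall back to a container/volume stub
        bits = [work.container]
        if work.volume:
            bits.append(work.volume)
        return " ".join(bits)


def write_coldp(entries: Sequence[MappingEntry], names: Sequence[NameRecord],
                works: Mapping[str, Work], out_dir,
                metadata: Optional[dict] = None) -> ColdpPackage:
    """Serialize matched entries as a CoLDP-style package in ``out_dir``.

    Works cited by several names are deduplicated into one reference row.
    Raises :class:`DanglingWorkError` when an entry cites an unknown
    work_id.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_lsid = {str(n.lsid): n for n in names}

    name_rows, ref_rows, unmapped = [], {}, []
    for entry in entries:
        lsid = str(entry.lsid)
        record = by_lsid.get(lsid)
        if not entry.matched:
            unmapped.append({
                "ID": lsid,
                "scientificName": record.name_string if record else "",
                "flags": ";".join(sorted(f.value for f in entry.flags)),
                "suggestedWork": entry.suggestion.work_id if entry.suggestion else "",
            })
            continue
        if entry.work_id not in works:
            raise DanglingWorkError(entry.work_id)
        work = works[entry.work_id]
        if not work.identifiers:
            # matched, but to a work with no persistent identifier: the
            # package only carries names mapped to an identifier
            unmapped.append({
                "ID": lsid,
                "scientificName": record.name_string if record else "",
                "flags": "no-identifier",
                "suggestedWork": work.work_id,
            })
            continue
        ref_id = assign_reference_id(work)
        ref_rows[ref_id] = {
            "ID": ref_id,
            "citation": _citation_of(work),
            "DOI": _doi_of(work.identifiers),
            "link": _link_of(work.identifiers),
            "remarks": "",
        }
        mc = record.microcitation if record else None
        name_rows.append({
            "ID": lsid,
            "scientificName": record.name_string if record else "",
            "rank": (record.rank or "") if record else "",
            "referenceID": ref_id,
            "page": "" if mc is None or mc.page is None else str(mc.page),
        })

    names_df = pd.DataFrame(name_rows, columns=NAME_COLUMNS).sort_values("ID") \
        if name_rows else pd.DataFrame(columns=NAME_COLUMNS)
    refs_df = (pd.DataFrame(sorted(ref_rows.values(), key=lambda r: r["ID"]),
                            columns=REFERENCE_COLUMNS)
               if ref_rows else pd.DataFrame(columns=REFERENCE_COLUMNS))
    meta = {"title": "Taxonomic names mapped to literature identifiers",
            "version": "1.0", **(metadata or {})}

    names_df.to_csv(out / NAMES_FILE, sep="\t", index=False, lineterminator="\n")
    refs_df.to_csv(out / REFERENCES_FILE, sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(unmapped, columns=["ID", "scientificName", "flags", "suggestedWork"]) \
        .sort_values("ID").to_csv(out / UNMAPPED_FILE, sep="\t", index=False,
                                  lineterminator="\n")
    with open(out / METADATA_FILE, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return ColdpPackage(names_df.reset_index(drop=True), refs_df, meta)


def read_coldp(package_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a package back; enforce referential integrity.

    Every referenceID in the names table must exist in the references
    table, else :class:`ReferentialIntegrityError`.
    """
    package_dir = Path(package_dir)
    names = pd.read_csv(package_dir / NAMES_FILE, sep="\t", dtype=str).fillna("")
    refs = pd.read_csv(package_dir / REFERENCES_FILE, sep="\t", dtype=str).fillna("")
    missing = set(names["referenceID"]) - set(refs["ID"]) if len(names) else set()
    if missing:
        raise ReferentialIntegrityError(
            f"names cite missing references: {sorted(missing)}")
    return names, refs
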