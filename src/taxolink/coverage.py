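"""Coverage statistics for name→literature mappings.

Three views of linking progress across nomenclators:

* a per-source counts table — total names, names with publication
  information, names per identifier kind, and an "Any" row counting names
  with at least one identifier of any kind, with a totals column summing
  across sources;
* a decade × container density matrix for the venues that published the
  most names, ordered by each venue's *modal decade* (the decade in which
  it published most names) with a per-venue persistent-identifier
  percentage — the view that exposes venue turnover over time;
* a long-tail curve: venues ranked by name count with the cumulative
  percentage of all names they account for.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .citation_model import NameRecord
from .identifiers import IdKind
from .match_engine import MappingEntry

__all__ = [
    "CoverageReport",
    "summarize_by_identifier",
    "add_totals",
    "coverage_percentage",
    "decade_container_matrix",
    "long_tail_curve",
    "published_counts",
]

TOTAL_NAMES = "TotalNames"
WITH_PUBLICATIONS = "NamesWithPublications"
ANY = "Any"
TOTAL_COL = "Total"

KIND_ROWS = [k.value for k in IdKind]
ROW_ORDER = [TOTAL_NAMES, WITH_PUBLICATIONS] + KIND_ROWS + [ANY]


@dataclass
class CoverageReport:
    counts: pd.DataFrame
    decade_matrix: Optional[pd.DataFrame] = None
    pid_percentages: Optional[pd.Series] = None
    long_tail: Optional[pd.DataFrame] = None


def add_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Append the totals column: each row summed across sources."""
    out = counts.copy()
    out[TOTAL_COL] = counts.sum(axis=1)
    return out


def summarize_by_identifier(entries: Sequence[MappingEntry],
                            names: Sequence[NameRecord]) -> pd.DataFrame:
    """Per-source counts by identifier kind, with a totals column.

    A name counts once per identifier *kind* it has (a name with a DOI
    and a URL adds 1 to DOI, 1 to URL and 1 to Any).  "Names with
    publications" counts names carrying any publication information
    (a parsed microcitation container).
    """
    by_lsid = {str(n.lsid): n for n in names}
    sources = sorted({n.source_db.value for n in names})
    counts = pd.DataFrame(0, index=ROW_ORDER, columns=sources, dtype="int64")
    for n in names:
        src = n.source_db.value
        counts.loc[TOTAL_NAMES, src] += 1
        if n.microcitation.container:
            counts.loc[WITH_PUBLICATIONS, src] += 1
    for entry in entries:
        record = by_lsid.get(str(entry.lsid))
        if record is None or not entry.identifiers:
            continue
        src = record.source_db.value
        for kind in {pid.kind for pid in entry.identifiers}:
            counts.loc[kind.value, src] += 1
        counts.loc[ANY, src] += 1
    return add_totals(counts)


def coverage_percentage(counts: pd.DataFrame, precision: int = 0) -> float:
    """Share of names-with-publications that gained at least one
    identifier: 100 × Any / NamesWithPublications, on the totals column."""
    denom = counts.loc[WITH_PUBLICATIONS, TOTAL_COL]
    if denom == 0:
        raise ZeroDivisionError("no names with publication information")
    return round(100.0 * counts.loc[ANY, TOTAL_COL] / denom, precision)


def published_counts() -> pd.DataFrame:
    """The published per-nomenclator identifier counts (Index Fungorum,
    IPNI, ION) shipped as package data, without the totals column."""
    with resources.files("taxolink.data").joinpath("published_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df.astype("int64")


def _decade(year: int, lo: int, hi: int) -> object:
    d = (year // 10) * 10
    if d < lo or d > hi:
        return "other"  # out of window: bucketed, never silently dropped
    return d


def decade_container_matrix(names_df: pd.DataFrame, top_k: int = 50,
                            year_range: tuple[int, int] = (1750, 2020),
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Decade × container name counts for the ``top_k`` venues.

    ``names_df`` needs columns container, year, has_pid.  Rows (containers)
    are ordered by modal decade (ties: earlier decade, then more names);
    undated names are excluded here but kept in the counts table, which
    has no year dimension.  Returns (matrix, per-container PID %).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    df = names_df.copy()
    pid_pct = (df.groupby("container")["has_pid"].mean() * 100.0
               if "has_pid" in df else pd.Series(dtype=float))
    top = df["container"].value_counts().head(top_k).index
    dated = df[df["container"].isin(top) & df["year"].notna()].copy()
    if dated.empty:
        return pd.DataFrame(), pid_pct.reindex(top).round(1)
    lo, hi = year_range
    dated["decade"] = dated["year"].astype(int).map(lambda y: _decade(y, lo, hi))
    matrix = (dated.pivot_table(index="container", columns="decade",
                                values="year", aggfunc="count", fill_value=0)
              .astype("int64"))
    numeric = [c for c in matrix.columns if c != "other"]
    matrix = matrix[sorted(numeric) + (["other"] if "other" in matrix.columns else [])]

    def order_key(container: str):
        row = matrix.loc[container, numeric]
        modal = row.idxmax() if len(numeric) and row.max() > 0 else 10**6
        return (modal, -int(matrix.loc[container].sum()), container)

    matrix = matrix.loc[sorted(matrix.index, key=order_key)]
    return matrix, pid_pct.reindex(matrix.index).round(1)


def long_tail_curve(names_df: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Venues ranked by descending name count with cumulative percentage
    of *all* names (not just the ranked ones).

    Ties rank lexicographically.  Columns: container, count, cumulative_pct.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    total = len(names_df)
    counts = names_df["container"].value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    rows, cum = [], 0
    for container, count in ranked:
        cum += count
        rows.append({"container": container, "count": int(count),
                     "cumulative_pct": 100.0 * cum / total if total else 0.0})
    return pd.DataFrame(rows, columns=["container", "count", "cumulative_pct"])
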