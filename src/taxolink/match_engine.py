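"""Resolve microcitations to works through a cascade of matching strategies.

Given a bibliography indexed by (container, volume) page ranges, a
microcitation such as ``MycoKeys 83: 166 (2021)`` is resolved by finding
the work in that volume whose page range contains page 166.  When page
matching fails, two weaker strategies follow: article-number matching
(continuous-numbering journals embed the article number in the DOI tail,
e.g. "issue no. 737541" ↔ DOI 10.3389/fmicb.2021.737541) and fuzzy
full-citation scoring.  A final diagnostic pass looks for journal/volume
mismatches — a page+volume that matches a *different* journal is a strong
clue the source record is in error — and attaches an advisory suggestion
without auto-accepting it.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .citation_model import AliasTable, MicroCitation, Work, normalize_container
from .errors import DuplicateWorkIdError
from .identifiers import IdKind, LSID

__all__ = [
    "Method",
    "Flag",
    "MatchConfig",
    "BibliographyIndex",
    "MappingEntry",
    "build_index",
    "resolve_microcitation",
    "match_article_number",
    "match_full_citation",
    "detect_mismatch",
    "resolve",
    "doi_tail",
]


class Method(str, Enum):
    PAGE_RANGE = "page_range"
    ARTICLE_NUMBER = "article_number"
    FULL_CITATION = "full_citation"
    EXISTING_ID = "existing_id"
    UNMATCHED = "unmatched"


class Flag(str, Enum):
    JOURNAL_VOLUME_MISMATCH = "journal_volume_mismatch"
    AMBIGUOUS = "ambiguous"
    YEAR_OFF_BY_ONE = "year_off_by_one"
    SUGGESTED_ALTERNATIVE = "suggested_alternative"


@dataclass(frozen=True)
class MatchConfig:
    """Tunable matching parameters.

    ``full_citation_threshold`` — minimum weighted similarity for the
    fuzzy path (default 0.8).  Weights sum to 1: container 0.4, exact
    volume 0.2, year within the window 0.2, author token overlap 0.2.
    ``year_window`` — tolerated publication-year drift (issue date vs
    actual publication date), default ±1.  ``continuous_k`` — when at
    least this many works in one (container, volume) all start on page 1
    the journal uses continuous article numbering and page containment is
    meaningless, so page matching is disabled for that key.
    """

    full_citation_threshold: float = 0.8
    w_container: float = 0.4
    w_volume: float = 0.2
    w_year: float = 0.2
    w_authors: float = 0.2
    year_window: int = 1
    continuous_k: int = 5


DEFAULT_CONFIG = MatchConfig()


@dataclass
class MappingEntry:
    """The outcome of resolving one name's microcitation."""

    lsid: Optional[LSID]
    work_id: Optional[str] = None
    identifiers: frozenset = field(default_factory=frozenset)
    method: Method = Method.UNMATCHED
    flags: frozenset = field(default_factory=frozenset)
    suggestion: Optional[Work] = None

    def __post_init__(self):
        self.identifiers = frozenset(self.identifiers)
        self.flags = frozenset(self.flags)
        if (self.method is Method.UNMATCHED) != (self.work_id is None):
            raise ValueError("method is unmatched iff work_id is absent")

    @property
    def matched(self) -> bool:
        return self.work_id is not None


def doi_tail(doi_value: str) -> str:
    """Final dot- or slash-delimited token of a DOI — for journals with
    continuous article numbering this is usually the article number."""
    return re.split(r"[./]", doi_value)[-1]


@dataclass
class BibliographyIndex:
    """Bibliography indexed for microcitation resolution.

    ``by_container_volume`` maps (canonical container, volume) to works
    ordered by (page_start, work_id); ``by_article_number`` maps article
    tokens (explicit field or DOI tail) to works.  ``continuous_keys``
    marks keys where page matching is disabled.
    """

    by_container_volume: dict = field(default_factory=dict)
    by_article_number: dict = field(default_factory=dict)
    works: list = field(default_factory=list)
    continuous_keys: set = field(default_factory=set)
    aliases: Optional[AliasTable] = None


def _key(container: str, volume: Optional[str], aliases: Optional[AliasTable]):
    return (normalize_container(container, aliases), volume)


def build_index(works: Sequence[Work], aliases: Optional[AliasTable] = None,
                config: MatchConfig = DEFAULT_CONFIG) -> BibliographyIndex:
    """Index works by (container, volume) page ranges and by article number."""
    index = BibliographyIndex(aliases=aliases)
    seen: set[str] = set()
    for work in works:
        if work.work_id in seen:
            raise DuplicateWorkIdError(f"duplicate work_id {work.work_id!r}")
        seen.add(work.work_id)
        index.works.append(work)
        index.by_container_volume.setdefault(_key(work.container, work.volume, aliases),
                                             []).append(work)
        tokens = set()
        if work.article_number:
            tokens.add(work.article_number)
        for pid in work.identifiers:
            if pid.kind is IdKind.DOI:
                tokens.add(doi_tail(pid.value))
        for tok in tokens:
            index.by_article_number.setdefault(tok, []).append(work)
    for key, bucket in index.by_container_volume.items():
        bucket.sort(key=lambda w: (w.page_start if w.page_start is not None else 10**9,
                                   w.work_id))
        if sum(1 for w in bucket if w.page_start == 1) >= config.continuous_k:
            index.continuous_keys.add(key)
    for bucket in index.by_article_number.values():
        bucket.sort(key=lambda w: w.work_id)
    return index


def _year_ok(mc_year: Optional[int], work_year: Optional[int], window: int) -> bool:
    if mc_year is None or work_year is None:
        return True
    return abs(mc_year - work_year) <= window


def _year_flags(mc_year: Optional[int], work_year: Optional[int]) -> set:
    if mc_year is not None and work_year is not None and abs(mc_year - work_year) == 1:
        return {Flag.YEAR_OFF_BY_ONE}
    return set()


def _containing(mc: MicroCitation, bucket: Iterable[Work], window: int) -> list[Work]:
    return [w for w in bucket
            if w.page_start is not None and w.page_end is not None
            and w.page_start <= mc.page <= w.page_end
            and _year_ok(mc.year, w.year, window)]


def _best_containing(mc: MicroCitation, candidates: Sequence[Work]) -> Work:
    # narrowest range first, then exact start-page hit, then lowest work_id
    return min(candidates, key=lambda w: (w.page_end - w.page_start,
                                          0 if w.page_start == mc.page else 1,
                                          w.work_id))


def _entry_for(lsid, work: Work, method: Method, flags: set) -> MappingEntry:
    return MappingEntry(lsid=lsid, work_id=work.work_id, identifiers=work.identifiers,
                        method=method, flags=frozenset(flags))


def resolve_microcitation(mc: MicroCitation, index: BibliographyIndex,
                          lsid: Optional[LSID] = None,
                          config: MatchConfig = DEFAULT_CONFIG) -> MappingEntry:
    """Resolve a microcitation by the cascade page_range → article_number →
    full_citation, stopping at the first success.

    Page matching requires exactly one work under the (container, volume)
    key whose page range contains the cited page with year within the
    window; multiple containing works are resolved by the tie-break rule
    and flagged ambiguous.
    """
    continuous_target = False
    if mc.page is not None and mc.volume is not None:
        key = (mc.container, mc.volume)
        continuous_target = key in index.continuous_keys
        if not continuous_target:
            candidates = _containing(mc, index.by_container_volume.get(key, ()),
                                     config.year_window)
            if candidates:
                best = _best_containing(mc, candidates)
                flags = _year_flags(mc.year, best.year)
                if len(candidates) > 1:
                    flags.add(Flag.AMBIGUOUS)
                return _entry_for(lsid, best, Method.PAGE_RANGE, flags)
    if mc.article_number is not None:
        entry = match_article_number(mc, index, lsid=lsid)
        if entry.matched:
            return entry
    if continuous_target:
        # continuous-numbering venue: page containment is meaningless and
        # the article-number path is the only admissible evidence
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    entry = match_full_citation(mc, index.works, config.full_citation_threshold,
                                lsid=lsid, aliases=index.aliases, config=config)
    if entry.matched:
        return entry
    return MappingEntry(lsid=lsid, method=Method.UNMATCHED)


def match_article_number(mc: MicroCitation, index: BibliographyIndex,
                         lsid: Optional[LSID] = None) -> MappingEntry:
    """Match on a shared article number (explicit field or DOI tail).

    Requires container agreement; a volume disagreement is tolerated but
    flagged journal_volume_mismatch.  Two container-agreeing candidates
    tie → ambiguous flag, lowest work_id wins.
    """
    if mc.article_number is None:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    pool = index.by_article_number.get(mc.article_number, ())
    same_container = [w for w in pool
                      if normalize_container(w.container, index.aliases) == mc.container]
    if not same_container:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    flags: set = set()
    if len(pool) > 1 and len(same_container) > 1:
        flags.add(Flag.AMBIGUOUS)
    best = same_container[0]
    if mc.volume is not None and best.volume is not None and mc.volume != best.volume:
        flags.add(Flag.JOURNAL_VOLUME_MISMATCH)
    return _entry_for(lsid, best, Method.ARTICLE_NUMBER, flags)


def _container_sim(a: str, b: str) -> float:
    if a == b:
        return 1.0
    return difflib.SequenceMatcher(None, a.lower(), b.lower()).ratio() * 0.5


def _token_overlap(a: Optional[str], b: Sequence[str]) -> float:
    """Jaccard overlap of author-block tokens; vacuously 1 when both empty."""
    ta = set(re.findall(r"\w+", a.lower())) if a else set()
    tb = set(t for name in b for t in re.findall(r"\w+", name.lower()))
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def citation_similarity(mc: MicroCitation, work: Work,
                        aliases: Optional[AliasTable] = None,
                        config: MatchConfig = DEFAULT_CONFIG) -> float:
    """Weighted similarity between a citation and a work in [0, 1].

    Components (a field absent on both sides counts as agreement):
    container (soft), exact volume, year within the window, author-token
    overlap.
    """
    wc = normalize_container(work.container, aliases)
    qc = normalize_container(mc.container, aliases)
    s = config.w_container * _container_sim(qc, wc)
    if mc.volume is None and work.volume is None:
        s += config.w_volume
    elif mc.volume is not None and work.volume is not None and mc.volume == work.volume:
        s += config.w_volume
    if mc.year is None and work.year is None:
        s += config.w_year
    elif mc.year is not None and work.year is not None \
            and abs(mc.year - work.year) <= config.year_window:
        s += config.w_year
    s += config.w_authors * _token_overlap(mc.authors, work.authors)
    return s


def match_full_citation(mc: MicroCitation, works: Sequence[Work],
                        threshold: float = DEFAULT_CONFIG.full_citation_threshold,
                        lsid: Optional[LSID] = None,
                        aliases: Optional[AliasTable] = None,
                        config: MatchConfig = DEFAULT_CONFIG) -> MappingEntry:
    """Fuzzy full-citation match: highest scorer strictly above the
    threshold wins; ties flagged ambiguous and broken by work_id.
    Deterministic given its inputs."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scored = sorted(((citation_similarity(mc, w, aliases, config), w) for w in works),
                    key=lambda sw: (-sw[0], sw[1].work_id))
    if not scored or scored[0][0] <= threshold:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    best_score, best = scored[0]
    flags = _year_flags(mc.year, best.year)
    if len(scored) > 1 and scored[1][0] == best_score:
        flags.add(Flag.AMBIGUOUS)
    return _entry_for(lsid, best, Method.FULL_CITATION, flags)


def detect_mismatch(mc: MicroCitation, index: BibliographyIndex,
                    lsid: Optional[LSID] = None,
                    config: MatchConfig = DEFAULT_CONFIG) -> MappingEntry:
    """Diagnose a journal/volume mismatch for an unresolved microcitation.

    Searches every *other* container for a work with the same volume token
    whose page range contains the cited page (year within the window).
    Exactly one qualifying alternative container → an unmatched entry
    flagged {journal_volume_mismatch, suggested_alternative} carrying the
    suggested work; several → ambiguous, no suggestion.  Citations
    carrying an article number instead of a page get the analogous
    diagnosis: a work in a different container whose article number (or
    DOI tail) equals the token is suggested, article numbers being
    effectively unique.  Suggestions are advisory only: the method stays
    unmatched.
    """
    alternatives: dict[str, list[Work]] = {}
    if mc.article_number is not None:
        for w in index.by_article_number.get(mc.article_number, ()):
            container = normalize_container(w.container, index.aliases)
            if container != mc.container:
                alternatives.setdefault(container, []).append(w)
        if len(alternatives) == 1:
            hits = next(iter(alternatives.values()))
            return MappingEntry(
                lsid=lsid, method=Method.UNMATCHED,
                suggestion=min(hits, key=lambda w: w.work_id),
                flags=frozenset({Flag.JOURNAL_VOLUME_MISMATCH,
                                 Flag.SUGGESTED_ALTERNATIVE}))
        if len(alternatives) > 1:
            return MappingEntry(lsid=lsid, method=Method.UNMATCHED,
                                flags=frozenset({Flag.AMBIGUOUS}))
    if mc.page is None or mc.volume is None:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    for (container, volume), bucket in index.by_container_volume.items():
        if container == mc.container or volume != mc.volume:
            continue
        if (container, volume) in index.continuous_keys:
            continue
        hits = _containing(mc, bucket, config.year_window)
        if hits:
            alternatives[container] = hits
    if not alternatives:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED)
    if len(alternatives) > 1:
        return MappingEntry(lsid=lsid, method=Method.UNMATCHED,
                            flags=frozenset({Flag.AMBIGUOUS}))
    hits = next(iter(alternatives.values()))
    return MappingEntry(
        lsid=lsid, method=Method.UNMATCHED, suggestion=_best_containing(mc, hits),
        flags=frozenset({Flag.JOURNAL_VOLUME_MISMATCH, Flag.SUGGESTED_ALTERNATIVE}))


def resolve(mc: MicroCitation, index: BibliographyIndex,
            lsid: Optional[LSID] = None,
            config: MatchConfig = DEFAULT_CONFIG) -> MappingEntry:
    """Full resolution: the matching cascade, then mismatch diagnosis for
    anything left unmatched."""
    entry = resolve_microcitation(mc, index, lsid=lsid, config=config)
    if entry.matched:
        return entry
    return detect_mismatch(mc, index, lsid=lsid, config=config)
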