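"""Matching cascade: page-range containment, the article-number
heuristic, fuzzy full-citation scoring and journal/volume mismatch
diagnosis — each checked against brute-force oracles."""

import pytest

from taxolink.citation_model import MicroCitation, Work
from taxolink.errors import DuplicateWorkIdError
from taxolink.identifiers import IdKind, PersistentIdentifier
from taxolink.match_engine import (DEFAULT_CONFIG, Flag, MatchConfig, Method,
                                   build_index, citation_similarity,
                                   detect_mismatch, match_article_number,
                                   match_full_citation, resolve,
                                   resolve_microcitation)
from taxolink.synth import CorpusSpec, generate_corpus


def mc(container, volume=None, page=None, year=None, artnum=None, authors=None):
    return MicroCitation(raw="", container=container, volume=volume, page=page,
                         year=year, article_number=artnum, authors=authors)


def brute_force_page_match(query, works, config=DEFAULT_CONFIG):
    """Independent O(N) oracle: scan every work for containment under the
    same tie-break rule, honouring the continuous-numbering exclusion."""
    if query.page is None or query.volume is None:
        return None
    starts_at_one = sum(1 for w in works
                        if w.container == query.container and w.volume == query.volume
                        and w.page_start == 1)
    if starts_at_one >= config.continuous_k:
        return None
    hits = [w for w in works
            if w.container == query.container and w.volume == query.volume
            and w.page_start is not None and w.page_end is not None
            and w.page_start <= query.page <= w.page_end
            and (query.year is None or w.year is None
                 or abs(query.year - w.year) <= config.year_window)]
    if not hits:
        return None
    return min(hits, key=lambda w: (w.page_end - w.page_start,
                                    0 if w.page_start == query.page else 1,
                                    w.work_id))


class TestBuildIndex:
    def test_distinct_keys_and_counts(self, mycokeys_work, frontiers_work):
        other = Work(work_id="w3", container="ZooKeys", volume="1",
                     page_start=1, page_end=9, year=2000)
        index = build_index([mycokeys_work, frontiers_work, other])
        assert len(index.by_container_volume) == 3
        assert all(len(v) == 1 for v in index.by_container_volume.values())

    def test_empty_input(self):
        index = build_index([])
        assert index.by_container_volume == {} and index.works == []

    def test_shared_key_ordered_by_page_start(self):
        a = Work(work_id="b", container="J", volume="1", page_start=10, page_end=30)
        b = Work(work_id="a", container="J", volume="1", page_start=5, page_end=20)
        index = build_index([a, b])
        bucket = index.by_container_volume[("J", "1")]
        assert [w.work_id for w in bucket] == ["a", "b"]

    def test_duplicate_work_id_rejected(self, mycokeys_work):
        with pytest.raises(DuplicateWorkIdError):
            build_index([mycokeys_work, mycokeys_work])

    def test_continuous_numbering_key_detected(self):
        works = [Work(work_id=f"w{i}", container="Frontiers", volume="12",
                      page_start=1, page_end=10 + i, year=2021,
                      article_number=str(700000 + i))
                 for i in range(5)]
        index = build_index(works)
        assert ("Frontiers", "12") in index.continuous_keys


class TestResolveMicrocitation:
    def test_page_range_match(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = resolve_microcitation(mc("MycoKeys", "83", 166, 2021), index)
        assert entry.method is Method.PAGE_RANGE
        assert entry.work_id == "mycokeys-83-72325"
        assert PersistentIdentifier(IdKind.DOI, "10.3897/mycokeys.83.72325") \
            in entry.identifiers

    def test_page_outside_every_range(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = resolve_microcitation(mc("MycoKeys", "83", 999, 2021), index)
        assert entry.method is Method.UNMATCHED and entry.work_id is None

    def test_ambiguous_tie_broken_by_narrower_range(self):
        wide = Work(work_id="wide", container="J", volume="1",
                    page_start=1, page_end=100, year=2000)
        narrow = Work(work_id="narrow", container="J", volume="1",
                      page_start=40, page_end=60, year=2000)
        index = build_index([wide, narrow])
        entry = resolve_microcitation(mc("J", "1", 50, 2000), index)
        assert entry.work_id == "narrow"
        assert Flag.AMBIGUOUS in entry.flags

    def test_year_off_by_one_tolerated_and_flagged(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = resolve_microcitation(mc("MycoKeys", "83", 166, 2022), index)
        assert entry.method is Method.PAGE_RANGE
        assert Flag.YEAR_OFF_BY_ONE in entry.flags

    def test_year_outside_window_rejected(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = resolve_microcitation(mc("MycoKeys", "83", 166, 2024), index)
        assert entry.method is Method.UNMATCHED

    def test_continuous_key_disables_page_matching(self):
        works = [Work(work_id=f"w{i}", container="Frontiers", volume="12",
                      page_start=1, page_end=15, year=2021,
                      article_number=str(700000 + i)) for i in range(6)]
        index = build_index(works)
        entry = resolve_microcitation(mc("Frontiers", "12", 5, 2021), index)
        assert entry.method is Method.UNMATCHED

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        corpus = generate_corpus(CorpusSpec(n_journals=6, seed=seed))
        index = build_index(corpus.works, corpus.aliases)
        for record in corpus.names:
            query = record.microcitation
            if query.page is None:
                continue
            expected = brute_force_page_match(query, corpus.works)
            entry = resolve_microcitation(query, index)
            if expected is None:
                assert entry.method is not Method.PAGE_RANGE
            else:
                assert entry.method is Method.PAGE_RANGE
                assert entry.work_id == expected.work_id


class TestArticleNumber:
    def test_shared_doi_tail_matches(self, frontiers_work):
        index = build_index([frontiers_work])
        entry = match_article_number(
            mc("Frontiers in Microbiology", "12", artnum="737541"), index)
        assert entry.method is Method.ARTICLE_NUMBER
        assert entry.work_id == "fmicb-737541"

    def test_unknown_token_unmatched(self, frontiers_work):
        index = build_index([frontiers_work])
        entry = match_article_number(
            mc("Frontiers in Microbiology", "12", artnum="000000"), index)
        assert entry.method is Method.UNMATCHED

    def test_volume_disagreement_flagged(self, frontiers_work):
        index = build_index([frontiers_work])
        entry = match_article_number(
            mc("Frontiers in Microbiology", "99", artnum="737541"), index)
        assert entry.method is Method.ARTICLE_NUMBER
        assert Flag.JOURNAL_VOLUME_MISMATCH in entry.flags

    def test_tie_needs_container_agreement(self):
        a = Work(work_id="a", container="J One", volume="1",
                 identifiers=frozenset({PersistentIdentifier(IdKind.DOI, "10.1/x.111")}))
        b = Work(work_id="b", container="J Two", volume="1",
                 identifiers=frozenset({PersistentIdentifier(IdKind.DOI, "10.2/y.111")}))
        index = build_index([a, b])
        entry = match_article_number(mc("J Two", "1", artnum="111"), index)
        assert entry.work_id == "b"
        assert Flag.AMBIGUOUS not in entry.flags


class TestFullCitation:
    def work(self):
        return Work(work_id="w", container="Frontiers in Microbiology",
                    volume="12", year=2021, authors=("Hu", "Dai"))

    def test_identical_metadata_scores_one(self):
        q = mc("Frontiers in Microbiology", "12", year=2021, authors="Hu, Dai")
        assert citation_similarity(q, self.work()) == pytest.approx(1.0)
        entry = match_full_citation(q, [self.work()])
        assert entry.method is Method.FULL_CITATION

    def test_alias_container_counts_as_exact(self, aliases):
        q = mc("Front. Microbiol.", "12", year=2021, authors="Hu, Dai")
        score = citation_similarity(q, self.work(), aliases)
        assert score == pytest.approx(1.0)
        assert match_full_citation(q, [self.work()], aliases=aliases).matched

    def test_container_only_scores_04_and_fails_default_threshold(self):
        q = mc("Frontiers in Microbiology", "99", year=1900, authors="Nobody")
        assert citation_similarity(q, self.work()) == pytest.approx(0.4)
        assert not match_full_citation(q, [self.work()]).matched

    def test_raising_threshold_never_adds_matches(self, small_corpus):
        index_works = small_corpus.works
        queries = [n.microcitation for n in small_corpus.names[:40]]
        matched_at = []
        for threshold in (0.2, 0.5, 0.8, 0.95):
            matched_at.append(sum(
                1 for q in queries
                if match_full_citation(q, index_works, threshold).matched))
        assert matched_at == sorted(matched_at, reverse=True)


class TestDetectMismatch:
    def test_wrong_journal_gets_suggestion(self, mycokeys_work):
        """Volume+page match a different journal: suggest, never accept."""
        index = build_index([mycokeys_work])
        query = mc("IMA Fungus", "83", 166, 2021)
        assert resolve_microcitation(query, index).method is Method.UNMATCHED
        entry = detect_mismatch(query, index)
        assert entry.method is Method.UNMATCHED and entry.work_id is None
        assert entry.flags == {Flag.JOURNAL_VOLUME_MISMATCH,
                               Flag.SUGGESTED_ALTERNATIVE}
        assert entry.suggestion.work_id == "mycokeys-83-72325"

    def test_nothing_anywhere_no_suggestion(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = detect_mismatch(mc("IMA Fungus", "83", 9999, 2021), index)
        assert entry.suggestion is None and not entry.flags

    def test_two_alternative_containers_ambiguous(self, mycokeys_work):
        rival = Work(work_id="rival", container="ZooKeys", volume="83",
                     page_start=150, page_end=180, year=2021)
        index = build_index([mycokeys_work, rival])
        entry = detect_mismatch(mc("IMA Fungus", "83", 166, 2021), index)
        assert entry.suggestion is None
        assert entry.flags == {Flag.AMBIGUOUS}

    def test_article_number_mismatch_suggested(self, frontiers_work):
        index = build_index([frontiers_work])
        entry = detect_mismatch(mc("Wrong Journal", "12", artnum="737541"), index)
        assert entry.method is Method.UNMATCHED
        assert entry.suggestion.work_id == "fmicb-737541"
        assert Flag.JOURNAL_VOLUME_MISMATCH in entry.flags

    def test_never_returns_a_match(self, small_corpus):
        index = build_index(small_corpus.works, small_corpus.aliases)
        for record in small_corpus.names:
            entry = detect_mismatch(record.microcitation, index)
            assert entry.method is Method.UNMATCHED


class TestResolveCascade:
    def test_full_recovery_on_clean_corpus(self, small_corpus):
        index = build_index(small_corpus.works, small_corpus.aliases)
        for record in small_corpus.names:
            entry = resolve(record.microcitation, index, lsid=record.lsid)
            assert entry.work_id == small_corpus.ground_truth[str(record.lsid)]

    def test_cascade_prefers_page_range_over_weaker_evidence(self, mycokeys_work):
        index = build_index([mycokeys_work])
        entry = resolve(mc("MycoKeys", "83", 166, 2021, authors="Hu, Dai, Zhao"),
                        index)
        assert entry.method is Method.PAGE_RANGE
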