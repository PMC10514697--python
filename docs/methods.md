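# Methods

## Problem setting

Nomenclators cite the publication of a taxonomic name at page granularity
(a *microcitation*), while work-level persistent identifiers — DOIs,
Wikidata QIDs, Handles, JSTOR/BioStor/BHL links — identify whole articles
or books. The package links the two so that a name's LSID can be joined to
the wider bibliographic graph. The core assumption is that a bibliography
with pagination metadata is available: given start and end pages per
article, resolving `MycoKeys 83: 166 (2021)` reduces to a containment test
within the (container, volume) key.

## Matching model

Resolution is a cascade ordered by evidential strength, stopping at the
first success:

1. **page_range** — exactly one work whose `[page_start, page_end]`
   contains the cited page, under the canonicalised (container, volume)
   key, with years within the window. Multiple containing works are
   possible (a short treatment inside a larger monographic span); the tie
   break prefers the narrowest range, then a work starting exactly on the
   cited page, then the lowest work id, and the entry is flagged
   `ambiguous`.
2. **article_number** — for continuous-numbering venues. The cited token
   must equal a work's explicit article number or the final dot/slash
   token of its DOI. Container agreement is required; volume disagreement
   is tolerated but flagged. When at least K works (default 5) under one
   (container, volume) key all start on page 1, the venue is treated as
   continuous-numbering: page matching is disabled for that key and the
   article-number path is the only admissible evidence — a page citation
   into such a key is *not* allowed to fall through to fuzzy matching,
   because nearly every article would "contain" a small page number.
3. **full_citation** — weighted similarity with components container
   (soft; an alias-table hit counts as exact, otherwise a dampened
   sequence ratio capped at 0.5), exact volume, year within the window,
   and Jaccard overlap of author-block tokens. Weights default to
   0.4/0.2/0.2/0.2; a field absent on both sides counts as (vacuous)
   agreement, a field present on only one side as disagreement. A match
   requires a score strictly above the threshold (default 0.8): a record
   agreeing on container, volume and year but offering no author evidence
   scores exactly 0.8 and deliberately stays unmatched, since that is the
   signature of a page-corrupted citation rather than a full-citation
   variant.

Unmatched entries then pass through **mismatch diagnosis**: search every
*other* container for works matching the volume token and containing the
page (or, for article-number citations, carrying that article number).
Exactly one qualifying alternative container produces flags
`{journal_volume_mismatch, suggested_alternative}` plus the suggested work;
two or more produce only `ambiguous`. Suggestions are advisory: the method
always stays `unmatched`, because a journal/volume mismatch is evidence the
*source record* is wrong, and such corrections belong with a curator.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `year_window` | 1 year | tolerated drift between cited and actual year (issue vs publication date) |
| `full_citation_threshold` | 0.8 | minimum (exclusive) weighted similarity |
| `w_container, w_volume, w_year, w_authors` | 0.4, 0.2, 0.2, 0.2 | similarity weights |
| `continuous_k` | 5 works | page-1 starts per key before a venue counts as continuous-numbering |

Identifier precedence for choosing "the" identifier of a work is
DOI > Handle > JSTOR > BioStor > BHL > URL > PDF, reflecting citability;
the Wikidata QID is carried as a parallel identifier rather than a
competitor and therefore ranks last instead of being excluded, so a
QID-only work still yields an identifier. A URL ending `.pdf` is classed
as a PDF link — a working convention, since source databases do not record
the distinction. Index Fungorum and MycoBank LSIDs sharing an object id
are treated as interchangeable via a configurable equivalence-rule table.

## Exports

**CoLDP.** The checklist package carries a names table (ID = LSID,
scientificName, rank, referenceID, page) and a references table
(referenceID, citation, DOI, link, remarks) as UTF-8/LF TSV with fixed row
ordering, so identical inputs are byte-identical. Reference ids follow the
rule: Wikidata QID when present, else a sanitised form of the preferred
identifier (`doi-10-3897-mycokeys-83-72325`). Only names mapped to a work
*with* a persistent identifier enter the package; everything else goes to
an `unmapped.tsv` sidecar for audit. The column set is deliberately
minimal; the format is used as a carrier for exactly this mapping, not as
a full checklist vocabulary.

**RDF.** Names whose publication has a DOI (only those — the DOI is the
identifier other datasets can join on) are exported as exactly three
triples each: `a schema:TaxonName`, `schema:name`, and `schema:isBasedOn`
pointing at the `https://doi.org/` IRI. LSIDs stay in `urn:lsid:` form in
subject position, matching what the source databases mint. Person records
in an ORCID-export-like JSON shape are cleaned first (whitespace/control
stripping, missing-scheme repair for known hosts, invalid fields dropped,
the record rejected only when the ORCID itself is unrecoverable), then
emitted as type + name + one `schema:affiliation` per organisation + one
`schema:creator` (work → person) per DOI. Organisation nodes are minted
deterministically as `urn:org:{scheme}:{value}` so that two people sharing
a RINGGOLD id share a node. All vocabulary IRIs sit in one constants table
(`taxolink.kg.VOCAB`); the person vocabulary is an approximation of the
ORCID export model, which is not fully specified here. The affiliation
query is a single parameterised SPARQL join
(name → work → person → organisation) with an optional LSID-authority
prefix filter; a full SPARQL endpoint is out of scope.

## Coverage statistics

The counts table counts each name once per identifier *kind* it gained and
once in `Any`; "names with publications" means a parsed, non-empty
container. The totals column is a row sum across sources, and the overall
coverage percentage is `100 × Any / NamesWithPublications` on that column.
The decade × container matrix bins dated names into left-closed 10-year
decades over a configurable 1750–2020 window (out-of-window years land in
an explicit `other` bucket rather than vanishing); venues are ordered by
modal decade (ties: earlier decade, then more names) and annotated with a
per-venue PID percentage computed per *name* — per-work would be the other
defensible choice, and the difference is documented rather than hidden.
The long-tail curve ranks venues by descending name count with cumulative
percentages computed against all names in the source, not just the ranked
head.

## Synthetic corpora

The generator emulates the structure the matcher relies on, not the
statistics of real nomenclatural text: journals own volumes of articles
with contiguous, non-overlapping page ranges restarting at 1 per volume;
a configurable fraction of journals (default 0.2) uses continuous article
numbering (every article on page 1, the article number as the DOI tail);
regular articles receive a DOI with probability 0.8 and any work a QID
with probability 0.3 — roughly the density a recent, well-curated slice of
the literature shows, and high enough that every matching path is
exercised. Defaults of 10 journals × 3 volumes × 8 articles × 2 names give
480-name corpora; the acceptance experiments use 9 articles and 2–4 names
per article (540–1080 names) so each run clears 500 names while staying
inside seconds. Journals are assigned stratified, non-overlapping
publication eras across 1750–2015, which is what lets the year window
discriminate among venues that share volume numbers; microcitations are
rendered in the terse house style without author blocks. One
`random.Random(seed)` stream drives everything, and synthetic LSIDs use
the authority `example.org` so they cannot be mistaken for real ones.

The corruption model applies, independently per name: container swap to
another venue, volume ±1, page +10000 (guaranteed outside any range), year
±2 (outside the matching window), each with its own rate, and logs every
change. Consequences of the design: passing tests demonstrate the
algorithmic contracts (oracle equivalence, 100 % recovery without
corruption, ≥95 % correct suggestions under journal swaps) — they do not
demonstrate robustness to OCR noise, multi-part citations, Roman-numeral
pagination or non-Latin scripts, which real nomenclator data contain and
the parser only partially handles (Roman-numeral page tokens are parked in
the residue rather than guessed).

## Numerical and degenerate-input choices

Ties are broken deterministically everywhere (lexicographic value within
an identifier kind; work id as the final matcher tie break), so every
pipeline output is byte-reproducible. Empty inputs produce valid empty
outputs (header-only tables, empty graphs) rather than errors; a zero
denominator in the coverage percentage raises. Microcitation parsing is an
ordered alternation of three patterns (volume:page(year); volume, issue
no. n; volume(issue):page) with leading text treated as the author block;
parse failures carry the raw string and are reported, never dropped.
Matched works lacking any persistent identifier are excluded from the
CoLDP package (no reference id is derivable) and surfaced in the sidecar.

## Known limitations

Resolution never consults live services — no LSID resolution, CrossRef,
ORCID or Wikidata APIs; only fixture-shaped ingest is implemented. The
full-citation path has no per-field edit distance beyond the container
component, so heavily abbreviated author blocks depress scores. The
continuous-numbering rule needs `continuous_k` works under a key before it
triggers; sparsely represented continuous venues below that threshold fall
back to (meaningless but harmless) page matching against page-1 spans.
ION-style full citation strings embedded in LSID metadata are handled by
the same grammar as the page-style strings; a dedicated grammar would be
needed if their shape diverges.
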