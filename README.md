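# taxolink

Link taxonomic names to the literature that published them.

Nomenclators — databases of scientific names such as Index Fungorum, IPNI
and ION — mint persistent identifiers (LSIDs) for names, but record *where*
a name was published only as a terse **microcitation**: a pointer to a page
inside a publication, e.g. `IMA Fungus 83: 166 (2021)`. Modern bibliographic
infrastructure, by contrast, identifies whole **works** (DOIs, Wikidata
QIDs, Handles, JSTOR/BioStor/BHL links). `taxolink` bridges the two: it
resolves microcitations to work-level identifiers against a bibliography
indexed by page ranges, exports the resulting name↔publication mapping as a
CoLDP checklist package and as RDF N-Triples, assembles a small
names/publications/people knowledge graph, and reports coverage statistics.

## The method

Given a parsed microcitation (container, volume, page, year) and a
bibliography of works with page ranges, resolution is a cascade, strongest
evidence first:

1. **Page-range containment** — find the work under the (container, volume)
   key whose `[page_start, page_end]` contains the cited page, with the
   year within ±1 (publication-date vs issue-date drift). Several
   containing works are resolved by preferring the narrowest range, then
   an exact start-page hit, and flagged `ambiguous`.
2. **Article number** — journals with continuous article numbering start
   every article on page 1, so page containment is meaningless there;
   instead the article number cited as e.g. `issue no. 737541` is matched
   against the final token of each DOI (`10.3389/fmicb.2021.737541` —
   note the shared `737541`) or an explicit article-number field.
3. **Fuzzy full citation** — a weighted similarity (container 0.4, exact
   volume 0.2, year ±1 0.2, author-token overlap 0.2) with a match only
   strictly above the threshold (default 0.8).

Anything still unmatched gets a diagnostic pass: if the volume and page
match an article in a *different* journal, the record is flagged
`journal_volume_mismatch` and that work is attached as an advisory
suggestion — a common clue that the source record itself is in error —
never auto-accepted.

Because real database dumps are large and access-restricted, the package
ships a synthetic-corpus generator with ground truth and a corruption model
(wrong journal, perturbed volume, impossible page, drifted year), so the
whole pipeline is testable end to end from a single seed.

## Worked example

```python
from taxolink import Work, PersistentIdentifier, IdKind, parse_microcitation
from taxolink.match_engine import build_index, resolve

biblio = [Work(work_id="mk", container="MycoKeys", volume="83",
               page_start=161, page_end=175, year=2021,
               identifiers=frozenset({PersistentIdentifier(
                   IdKind.DOI, "10.3897/mycokeys.83.72325")}))]
index = build_index(biblio)

mc = parse_microcitation("Hu, Dai, Zhao, Guo, Tuo, Rao, Qi, Zhang, Li & Zhang, "
                         "IMA Fungus 83: 166 (2021)")
entry = resolve(mc, index)
print(entry.method.value, sorted(f.value for f in entry.flags),
      entry.suggestion.work_id)
```

prints

```
unmatched ['journal_volume_mismatch', 'suggested_alternative'] mk
```

— the citation claims *IMA Fungus* volume 83, but no such volume exists in
the bibliography; the volume and page do match a *MycoKeys* article, so the
resolver refuses the match and suggests the MycoKeys work for curation
instead.

The command line drives the same library:

```bash
taxolink simulate --seed 4 --out demo/           # synthetic corpus + ground truth
taxolink match --names demo/names.tsv --biblio demo/works.json \
               --aliases demo/aliases.tsv --out demo/mapping.tsv
taxolink export-coldp --names demo/names.tsv --biblio demo/works.json --out demo/coldp
taxolink kg-query --graph demo/names.nt --graph demo/persons.nt --org RINGGOLD:41803
taxolink lookup --names demo/names.tsv --biblio demo/works.json "Selladermacor mylep"
```

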