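# Methods

## The representation

An aTag is a pair *(text, tags)* plus provenance: a short human-readable
assertion and a set of ontology entities mentioned in or characterizing
it. No RDF properties between the tagged entities are asserted — the
convention consciously accepts that a statement like a multi-protein
interaction network cannot be captured without loss, in exchange for a
representation that is trivial to create, merge and query. The RDF
footprint of one aTag is fixed and small:

| aspect | property |
|---|---|
| the aTag | `rdf:type sioc:Item` |
| snippet text | `sioc:content` (plain literal; optional language tag) |
| each tag | `sioc:topic` → entity IRI |
| tag label | `rdfs:label` on the entity IRI |
| source document | `dcterms:source` |
| timestamp | `dcterms:created` (`xsd:dateTime`, UTC) |

This property set is centralized in `serialize.py` and can be re-pointed
in one place. SIOC is the natural host vocabulary (an aTag is a snippet
of online content with topics); the label triple is included so that
display labels survive Turtle round trips, where no anchor text exists.

## Identifier minting

aTags are meant to be copied between documents, so identifiers must be
stable under re-serialization and cosmetic editing. `mint_atag_uri`
returns `base_uri + "#atag-" + h` with *h* the first 12 hex characters
of SHA-256 over the NFC-normalized, whitespace-collapsed, trimmed text,
a newline, and the newline-joined *sorted* tag IRIs. Consequences, all
property-tested: minting is pure; permuting tags or changing internal
whitespace runs never changes the IRI; distinct assertions collide with
probability ~2⁻⁴⁸ per pair, negligible at realistic store sizes. The
display text itself is stored unmodified. Duplicate tag URIs collapse
silently to the first occurrence (first label wins) rather than
erroring, matching the permissive spirit of the convention.

## Serialization choices

* **RDFa dialect.** RDFa 1.1 attributes (`prefix`, `about`, `typeof`,
  `property`, `href`, `content`) on XHTML. Every emitted fragment
  declares its own prefix map, so copy-and-pasting a fragment carries
  its statements along — concatenating fragments yields exactly the
  union of their aTags (tested). The reader is a subset processor for
  this dialect implemented on lxml; it tracks the prefix environment and
  subject (`about`) down the tree and ignores unknown markup. Turtle
  reading/writing is delegated to rdflib.
* **Cross-checking.** The Turtle and RDFa serializations of a collection
  must embed identical triple sets. Since Turtle is parsed by rdflib and
  RDFa by this package's own processor, the equality check in the tests
  compares two independent parsing routes.
* **Ordering.** HTML preserves tag insertion order (display order);
  Turtle is set-oriented, so collections parsed from Turtle come back
  sorted by aTag identifier with tags sorted by IRI. `Atag.canonical()`
  provides the order-insensitive form for comparisons.
* **Vocabulary attribution.** The `source_vocabulary` tag of an entity
  (`dbpedia` / `obo` / `mesh` / `other`) is bookkeeping, not RDF
  content; parsers re-derive it from the IRI namespace
  (`guess_vocabulary`). Entities from unlisted namespaces round-trip as
  `other`.
* **Literals.** Snippet text is a plain literal with no language tag by
  default; a tag can be requested per call. RDF/XML is not written
  natively — any RDF tool can convert the Turtle.
* **Determinism.** For a fixed input and prefix map both serializers are
  byte-deterministic (verified across interpreter hash seeds).

## Abstract pipeline

`segment_abstract` matches explicit ALL-CAPS section headers followed by
a colon, case-sensitively, against a configurable vocabulary. The
default vocabulary covers common structured-abstract practice
(BACKGROUND, INTRODUCTION, OBJECTIVE(S), AIM(S), METHODS, MATERIALS AND
METHODS, RESULTS, FINDINGS, DISCUSSION, CONCLUSION(S), INTERPRETATION),
with synonyms mapped to canonical labels (AIM→OBJECTIVES,
FINDINGS→RESULTS, INTERPRETATION→CONCLUSIONS, ...). Longer headers win
over embedded shorter ones. Section text is the raw remainder after the
header token, whitespace preserved, so the sections exactly partition
the input — an invariant the tests assert byte-for-byte. Offsets are
0-based, half-open throughout.

`find_abbreviations` implements Schwartz–Hearst candidate/long-form
matching: a parenthesized candidate short form (2–10 characters, ≤2
words, ≥1 letter, first character alphanumeric) is paired with the
shortest word sequence ending just before the open parenthesis — within
a window of `min(|SF|+5, 2|SF|)` words — that contains all alphanumeric
short-form characters in order, case-insensitively, with the first
character anchored at a word start. `expand_abbreviations` substitutes
standalone occurrences only (word-bounded, case-sensitive, longest short
form first), so `SADNESS` and the plural `SADs` are deliberately left
untouched; conflicting re-definitions keep the first and log a warning.
The definition itself is not removed — only the conclusion section is
emitted anyway.

`extract_conclusion_atags` gathers definitions from the whole abstract,
expands the conclusion body, and emits one aTag per record tagged with
the record's MeSH descriptors (`http://id.nlm.nih.gov/mesh/` + UI — the
scheme is an injectable function) and provenance
`https://pubmed.ncbi.nlm.nih.gov/<pmid>/`. The aTag text is the
header-free section body: the header is segmentation metadata, not part
of the assertion. Retrieval is out of scope — inputs are local
line-delimited JSON records; the query string historically used to
assemble a conclusion-section corpus ships as documentation
(`PUBMED_CONCLUSION_QUERY`).

## Tabular conversion

A `MappingConfig` declares a text template over column names, entity
columns (URI from a prefix + cell, or verbatim from a second column;
label from the cell or a label column), an optional provenance template
and the delimiter. Quantitative cells (e.g. a Ki affinity) belong in the
text template only: emitting them as typed RDF literals would reintroduce
exactly the relational structure the convention gives up, so it is a
non-goal. Empty entity cells yield no tag. Strict mode (default) aborts
on the first unresolvable row; permissive mode skips and reports, and in
both modes `rows_read == emitted + skipped`.

## Explorer

Broader tags are the transitive closure over the union of
`skos:broader` and `rdfs:subClassOf` edges (narrower→broader),
computed with networkx; closures exclude the entity itself. Cycles are
tolerated — members of a strongly connected component see each other as
ancestors — but reported with a warning naming the cycle, since a
taxonomy should be a DAG. Unknown edge endpoints are auto-registered
with a label derived from the IRI local name.

Search semantics are conjunctive across all selections (the exploratory
narrow/un-focus interaction only ever intersects; disjunction is a
non-goal): keyword as case-insensitive substring of the snippet text or
a direct tag label (matching broader-tag labels too is available behind
a flag but off by default), selected tags against direct tag sets,
selected broader tags against expanded sets. Ranking is keyword
occurrence count with stable input-order tie-break — no corpus
statistics are involved, which keeps results reproducible. The broader
facet counts expanded-minus-direct entities per aTag, so an entity that
is both a direct tag and an ancestor of another tag of the same aTag is
not double-listed; facets are sorted by count, then label. Monotonicity
(adding a selection never grows the result set) and un-focus
reversibility are consequences of this design and are property-tested
over a thousand randomized query steps.

## Synthetic data

The generators in `fixtures.py` are pure functions of their parameters
(seeded PRNG, no clock or network) and return ground truth computed
independently of the processing code, so they serve as oracles:

* **Abstract corpus** — default 500 records, half structured (an exact
  count, rounded half-up, at deterministically sampled positions), 1–5
  MeSH-like descriptors each, and on average 1.5 planted abbreviation
  definitions per structured abstract. Planted long forms use 2–3 words
  with pairwise-distinct initials, which provably makes the
  shortest-match rule recover exactly the planted words; the acronym is
  the uppercased initials and is re-used in the conclusion sentence.
  Half structured is a convenient test mix, chosen so both branches of
  the pipeline are exercised equally — observed corpora are skewed
  toward unstructured abstracts (roughly one in seven carries an
  explicit conclusion header in the topic sample documented with the
  retrieval query).
* **Drug store** — a fixed named world (three pharmaceutical companies,
  six drugs under a class hierarchy with a `drug` root, side effects,
  and person/institution distractor statements that also mention company
  names); the seed only shuffles statement order. It is sized to make
  every step of the company→drug→class exploration scenario observable.
* **Side-effect table** — unique drug/effect pairs (so minted
  identifiers never collide), a configurable fraction of truncated rows
  (expected verdict: skip/abort), and occasional empty URI cells
  (expected verdict: one-tag aTag).

What the generated text does **not** emulate: natural-language variation
(sentences are template-assembled word salad), noisy or nested
parentheses, mixed-case headers, abbreviation edge cases outside the
matching rule (plural short forms, redefinitions across sections), or
ontologies with multiple labels per entity. Passing the recovery tests
therefore demonstrates correctness of the implemented rules, not
robustness of those rules on real prose — the segmentation and
abbreviation rules themselves are the standard ones, but their recall on
real abstracts is a property of the corpus, not of this code.

## Problem sizes and numerical choices

The test suite and the acceptance script run the round-trip suite on 200
generated collections, oracle equivalence on a 300-node random DAG (50
sampled nodes) and a 500-aTag store (100 random queries), pipeline
recovery on 500 abstracts, and 1,000 narrowing/un-focus steps — sizes at
which the brute-force oracles are still exact and instantaneous, and
comfortably beyond the scale at which the implementations take distinct
code paths. There is no floating-point arithmetic anywhere; every
comparison is exact (string, set or integer) and all timestamps are
fixed offsets from a constant epoch in UTC.

Corpus-scale figures associated with the original aTag datasets (on the
order of 10⁵–10⁶ RDF statements derived from live literature and
database dumps) require external resources and are documented here as
context only; nothing in this package claims to reproduce them.

## Known limitations

* The RDFa reader handles the dialect this package emits (plus harmless
  surrounding markup); it is not a general RDFa 1.1 processor (no
  `vocab`, `rel`/`rev`, chaining, or safe-CURIE handling).
* `sioc:Item` subjects lacking `sioc:content` are skipped with a
  warning, not recovered.
* Entity labels are single-valued; if a store asserts several
  `rdfs:label` values for one IRI, one is chosen.
* The IRI validator is syntactic and permissive (scheme plus non-empty
  remainder, no forbidden characters); it does not enforce full RFC 3987
  grammar.
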