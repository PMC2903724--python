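# atagkit

A toolkit for **aTags** ("associative tags"): short, human-readable
scientific assertions annotated with entities from established
ontologies and taxonomies (DBpedia, OBO ontologies, MeSH, ...), carried
as XHTML+RDFa snippets or Turtle so that one document serves both human
readers and machines.

An aTag deliberately asserts *no relations* between its entities. A
statement like *"Protein A interacts with protein B in tissue C at time
D"* is represented as the sentence itself plus a bag of five entity
tags — not as a convoluted RDF graph. The representation trades
expressivity for something rarer in the biomedical Semantic Web:
datasets that can be created by anyone, merged by copy-and-paste, and
queried uniformly. In RDF terms each aTag is a `sioc:Item` whose
`sioc:content` is the snippet text and whose `sioc:topic` links point at
the entity IRIs, with `dcterms:source` for provenance.

The toolkit is aimed at anyone mining key assertions from biomedical
literature and databases: it covers constructing and validating aTags,
deterministic identifier minting, lossless RDFa/Turtle round-tripping,
generating aTags from structured abstracts (section segmentation,
Schwartz–Hearst abbreviation expansion, MeSH tagging) and from tabular
database dumps (declarative column mapping), and faceted exploration of
aTag stores with *broader tags* inferred by transitive closure over
`skos:broader` / `rdfs:subClassOf` hierarchies.

## Worked example

```python
from atagkit import OntologyEntity, AtagCollection, make_atag, atags_to_turtle

atag = make_atag(
    "Huperzine A acts as a non-competitive antagonist of the NMDA receptor",
    [OntologyEntity("http://dbpedia.org/resource/Huperzine_A",
                    "Huperzine A", "dbpedia"),
     OntologyEntity("http://purl.obolibrary.org/obo/GO_0048019",
                    "receptor antagonist activity", "obo"),
     OntologyEntity("http://dbpedia.org/resource/NMDA_receptor",
                    "NMDA receptor", "dbpedia")],
    provenance_uri="https://pubmed.ncbi.nlm.nih.gov/18771181/",
    base_uri="http://example.org/atags")

print(atags_to_turtle(AtagCollection("http://example.org/atags", [atag])))
```

prints

```turtle
@prefix dcterms: <http://purl.org/dc/terms/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix sioc: <http://rdfs.org/sioc/ns#> .

<http://example.org/atags#atag-5db8992fe404> a sioc:Item ;
    dcterms:source <https://pubmed.ncbi.nlm.nih.gov/18771181/> ;
    sioc:content "Huperzine A acts as a non-competitive antagonist of the NMDA receptor" ;
    sioc:topic <http://dbpedia.org/resource/Huperzine_A>,
        <http://dbpedia.org/resource/NMDA_receptor>,
        <http://purl.obolibrary.org/obo/GO_0048019> .

<http://dbpedia.org/resource/Huperzine_A> rdfs:label "Huperzine A" .

<http://dbpedia.org/resource/NMDA_receptor> rdfs:label "NMDA receptor" .

<http://purl.obolibrary.org/obo/GO_0048019> rdfs:label "receptor antagonist activity" .
```

One assertion, three entity tags, one deterministically minted
identifier (`#atag-` + the first 12 hex digits of a SHA-256 over the
normalized text and sorted tag IRIs — the same statement with the same
tags always mints the same IRI). `atag_to_rdfa` emits the equivalent
self-contained HTML snippet; `rdfa_to_atags` / `turtle_to_atags` parse
either serialization back without loss.

### Command line

```sh
atag fixtures corpus --seed 1 --n 50 --out-dir demo      # synthetic abstracts
atag extract demo/records.jsonl -o demo/atags.ttl        # conclusions -> aTags
atag validate demo/atags.ttl                             # invariants + round trip
atag fixtures store --out-dir demo                       # drug/company world
atag query demo/store.ttl --ontology demo/ontology.ttl \
     -k Pfizer -b http://dbpedia.org/resource/Drug
```

The last command narrows a keyword search for "Pfizer" to statements
whose tags have `drug` among their inferred broader tags and prints the
four matching drug statements with live tag / broader-tag facet counts
(e.g. `1 pyrazole`, `1 statin`, `1 antibiotic`).

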