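"""Faceted search over aTag stores with ontology-inferred broader tags.

Because aTags borrow their tags from shared ontologies and taxonomies,
a collection of them can be explored far beyond plain keyword search:
every tag inherits its ancestors ("broader tags") through ``skos:broader``
and ``rdfs:subClassOf`` links, so a statement tagged ``Celecoxib`` is
also findable under ``pyrazole`` or ``drug`` even though neither word
occurs in it.  The explorer exposes this as two conjunctive facet
dimensions -- direct tags and broader tags -- with live counts, plus
case-insensitive keyword search over snippet text and tag labels.

Search semantics: an aTag matches iff the keyword (if any) is a
substring of its text or of one of its tag labels, AND it carries every
selected tag directly, AND every selected broader tag is in its expanded
tag set (direct tags plus the broader closure of each).  Results are
ranked by keyword occurrence count, ties broken by stable input order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
from rdflib import Graph as RdfGraph
from rdflib.namespace import RDFS, SKOS, RDF

from .model import Atag, AtagCollection, OntologyEntity, guess_vocabulary

__all__ = [
    "OntologyGraph",
    "FacetQuery",
    "ResultSet",
    "AtagIndex",
    "broader_closure",
    "build_index",
    "search",
    "focus_entity",
    "load_ontology_turtle",
    "load_ontology_edge_lists",
    "ontology_to_turtle",
]

logger = logging.getLogger(__name__)


def _label_from_uri(uri: str) -> str:
    tail = uri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return tail.replace("_", " ") or uri


class OntologyGraph:
    """Labeled entities joined by directed narrower-to-broader edges.

    Edges are the union of subclass and SKOS-broader style links.  The
    graph is treated as a DAG; cycles are detected and reported with a
    warning naming one offending cycle, and closure computation still
    terminates (all members of a strongly connected component share one
    ancestor set).
    """

    def __init__(self):
        self.entities: dict[str, OntologyEntity] = {}
        self._g = nx.DiGraph()

    def add_entity(self, entity: OntologyEntity) -> None:
        self.entities[entity.uri] = entity
        self._g.add_node(entity.uri)

    def _ensure(self, uri: str) -> None:
        if uri not in self.entities:
            self.add_entity(OntologyEntity(
                uri=uri, preferred_label=_label_from_uri(uri),
                source_vocabulary=guess_vocabulary(uri)))

    def add_broader_edge(self, narrower: str, broader: str) -> None:
        """Register *narrower* -> *broader*; unknown endpoints are
        auto-registered with a label derived from the URI local name."""
        self._ensure(narrower)
        self._ensure(broader)
        self._g.add_edge(narrower, broader)

    @property
    def broader_edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges())

    def entity(self, uri: str) -> OntologyEntity:
        """The entity for *uri*, synthesized from the URI if unknown."""
        if uri in self.entities:
            return self.entities[uri]
        return OntologyEntity(uri=uri, preferred_label=_label_from_uri(uri),
                              source_vocabulary=guess_vocabulary(uri))

    def check_cycles(self) -> list[list[str]]:
        """Report cycles (empty for a well-formed taxonomy)."""
        if nx.is_directed_acyclic_graph(self._g):
            return []
        cycle = [u for u, _v in nx.find_cycle(self._g)]
        logger.warning("ontology contains a cycle: %s", " -> ".join(cycle))
        return [cycle]

    def ancestors(self, uri: str) -> set[str]:
        if uri not in self._g:
            return set()
        return nx.descendants(self._g, uri)


def broader_closure(uri: str, g: OntologyGraph) -> set[str]:
    """All proper ancestors of *uri* reachable over broader edges.

    Self is excluded; an unknown URI has an empty closure.  Pure function
    of (uri, graph), safe to memoize.
    """
    return g.ancestors(uri)


# ---------------------------------------------------------------------------
# Ontology loading
# ---------------------------------------------------------------------------

def load_ontology_turtle(ttl: str) -> OntologyGraph:
    """Build an ontology graph from Turtle text.

    Broader edges come from ``skos:broader`` and ``rdfs:subClassOf``;
    labels from ``skos:prefLabel`` or ``rdfs:label`` (preferred in that
    order).  Blank nodes are ignored.
    """
    rg = RdfGraph()
    rg.parse(data=ttl, format="turtle")
    g = OntologyGraph()
    labels: dict[str, str] = {}
    for s, p, o in rg:
        if p in (SKOS.prefLabel, RDFS.label):
            key = str(s)
            if p == SKOS.prefLabel or key not in labels:
                labels[key] = str(o)
    for s, p, o in rg:
        if p in (SKOS.broader, RDFS.subClassOf):
            if not str(s).startswith("_:") and not str(o).startswith("_:"):
                g.add_broader_edge(str(s), str(o))
    for uri, label in labels.items():
        g.add_entity(OntologyEntity(uri=uri, preferred_label=label,
                                    source_vocabulary=guess_vocabulary(uri)))
    g.check_cycles()
    return g


def ontology_to_turtle(g: OntologyGraph) -> str:
    """Serialize an ontology graph as Turtle (``skos:broader`` edges plus
    ``rdfs:label`` for every entity); inverse of :func:`load_ontology_turtle`
    up to label-source preference."""
    rg = RdfGraph(bind_namespaces="none")
    rg.bind("skos", SKOS, replace=True)
    rg.bind("rdfs", RDFS, replace=True)
    from rdflib import Literal, URIRef
    for uri in sorted(g.entities):
        rg.add((URIRef(uri), RDFS.label, Literal(g.entities[uri].preferred_label)))
    for narrower, broader in sorted(g.broader_edges):
        rg.add((URIRef(narrower), SKOS.broader, URIRef(broader)))
    return rg.serialize(format="turtle")


def load_ontology_edge_lists(
    edges: Union[str, Path, Iterable[str]],
    labels: Union[str, Path, Iterable[str], None] = None,
) -> OntologyGraph:
    """Build an ontology graph from 2-column TSV files.

    *edges* holds ``narrower<TAB>broader`` URI pairs; optional *labels*
    holds ``uri<TAB>label`` pairs.  Lines starting with ``#`` are skipped.
    """
    def _rows(src):
        if isinstance(src, (str, Path)):
            text = Path(src).read_text(encoding="utf-8").splitlines()
        else:
            text = src
        for row in csv.reader(text, delimiter="\t"):
            if row and not row[0].startswith("#"):
                yield row

    g = OntologyGraph()
    for row in _rows(edges):
        if len(row) < 2:
            raise ValueError(f"edge row needs 2 columns, got {row!r}")
        g.add_broader_edge(row[0].strip(), row[1].strip())
    if labels is not None:
        for row in _rows(labels):
            if len(row) >= 2:
                g.add_entity(OntologyEntity(
                    uri=row[0].strip(), preferred_label=row[1].strip(),
                    source_vocabulary=guess_vocabulary(row[0].strip())))
    g.check_cycles()
    return g


# ---------------------------------------------------------------------------
# Index and query
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FacetQuery:
    """Explorer query state: optional keyword plus conjunctive facet
    selections (direct-tag URIs and broader-tag URIs)."""

    keyword: Optional[str] = None
    selected_tags: frozenset[str] = frozenset()
    selected_broader: frozenset[str] = frozenset()

    def with_tag(self, uri: str) -> "FacetQuery":
        return FacetQuery(self.keyword, self.selected_tags | {uri}, self.selected_broader)

    def with_broader(self, uri: str) -> "FacetQuery":
        return FacetQuery(self.keyword, self.selected_tags, self.selected_broader | {uri})


@dataclass
class ResultSet:
    """Matching aTags plus facet values with live counts.

    ``tag_facet`` counts direct tags over the matching set;
    ``broader_facet`` counts inferred proper ancestors (expanded tag set
    minus direct tags, per aTag).  Both are sorted by count descending,
    then label ascending.
    """

    atags: list[Atag] = field(default_factory=list)
    tag_facet: list[tuple[OntologyEntity, int]] = field(default_factory=list)
    broader_facet: list[tuple[OntologyEntity, int]] = field(default_factory=list)

    def facet_uris(self, which: str = "broader") -> set[str]:
        facet = self.broader_facet if which == "broader" else self.tag_facet
        return {e.uri for e, _n in facet}


class AtagIndex:
    """A queryable view over a collection: per-aTag direct and expanded
    (closure-augmented) tag sets, entity lookup, and keyword fields."""

    def __init__(self, atags: list[Atag], ontology: OntologyGraph,
                 *, keyword_matches_broader_labels: bool = False):
        self.atags = atags
        self.ontology = ontology
        self.keyword_matches_broader_labels = keyword_matches_broader_labels
        self.direct: list[frozenset[str]] = []
        self.expanded: list[frozenset[str]] = []
        self._entity_cache: dict[str, OntologyEntity] = {}
        closure_memo: dict[str, set[str]] = {}
        for a in atags:
            uris = set(a.tag_uris())
            exp = set(uris)
            for u in uris:
                if u not in closure_memo:
                    closure_memo[u] = broader_closure(u, ontology)
                exp |= closure_memo[u]
            self.direct.append(frozenset(uris))
            self.expanded.append(frozenset(exp))
            for ent in a.tags:
                self._entity_cache.setdefault(ent.uri, ent)

    def entity(self, uri: str) -> OntologyEntity:
        if uri in self.ontology.entities:
            return self.ontology.entities[uri]
        if uri in self._entity_cache:
            return self._entity_cache[uri]
        return self.ontology.entity(uri)

    def _keyword_fields(self, i: int) -> list[str]:
        a = self.atags[i]
        fields = [a.text] + [t.preferred_label for t in a.tags]
        if self.keyword_matches_broader_labels:
            fields += [self.entity(u).preferred_label
                       for u in self.expanded[i] - self.direct[i]]
        return fields

    def matches(self, i: int, q: FacetQuery) -> bool:
        if q.keyword and q.keyword.strip():
            kw = q.keyword.strip().lower()
            if not any(kw in f.lower() for f in self._keyword_fields(i)):
                return False
        if not q.selected_tags <= self.direct[i]:
            return False
        if not q.selected_broader <= self.expanded[i]:
            return False
        return True

    def relevance(self, i: int, keyword: Optional[str]) -> int:
        if not keyword or not keyword.strip():
            return 0
        kw = keyword.strip().lower()
        return sum(f.lower().count(kw) for f in self._keyword_fields(i))


def build_index(c: AtagCollection, g: OntologyGraph,
                *, keyword_matches_broader_labels: bool = False) -> AtagIndex:
    """Index a collection against an ontology for faceted search."""
    return AtagIndex(list(c.atags), g,
                     keyword_matches_broader_labels=keyword_matches_broader_labels)


def _sorted_facet(counts: dict[str, int], idx: AtagIndex
                  ) -> list[tuple[OntologyEntity, int]]:
    entities = {u: idx.entity(u) for u in counts}
    return sorted(((entities[u], n) for u, n in counts.items()),
                  key=lambda pair: (-pair[1], pair[0].preferred_label, pair[0].uri))


def search(idx: AtagIndex, q: FacetQuery) -> ResultSet:
    """Evaluate a facet query: filter, rank, and compute facet counts.

    Adding any selection to *q* can only shrink the result set
    (conjunctive semantics), and removing it restores the previous set
    exactly -- the narrowing / un-focusing interaction of exploratory
    search.
    """
    hit_indices = [i for i in range(len(idx.atags)) if idx.matches(i, q)]
    hit_indices.sort(key=lambda i: (-idx.relevance(i, q.keyword), i))
    tag_counts: dict[str, int] = {}
    broader_counts: dict[str, int] = {}
    for i in hit_indices:
        for u in idx.direct[i]:
            tag_counts[u] = tag_counts.get(u, 0) + 1
        for u in idx.expanded[i] - idx.direct[i]:
            broader_counts[u] = broader_counts.get(u, 0) + 1
    return ResultSet(
        atags=[idx.atags[i] for i in hit_indices],
        tag_facet=_sorted_facet(tag_counts, idx),
        broader_facet=_sorted_facet(broader_counts, idx))


def focus_entity(idx: AtagIndex, uri: str) -> ResultSet:
    """Everything known about one entity: all aTags carrying it as a
    direct tag, with facets (equivalent to selecting it as a tag facet
    with no keyword)."""
    return search(idx, FacetQuery(selected_tags=frozenset({uri})))
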