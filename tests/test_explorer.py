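"""Explorer: broader-tag closure and faceted search, checked against
independent brute-force oracles."""

import random
from collections import deque

import pytest

from atagkit import AtagCollection, OntologyEntity, make_atag
from atagkit.explorer import (
    AtagIndex,
    FacetQuery,
    OntologyGraph,
    broader_closure,
    build_index,
    focus_entity,
    load_ontology_edge_lists,
    load_ontology_turtle,
    ontology_to_turtle,
    search,
)
from atagkit.fixtures import gen_drug_store

from conftest import BASE

DBP = "http://dbpedia.org/resource/"


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bfs_ancestors(edges, start):
    """Plain BFS over an edge set; the oracle for broader_closure."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    seen, queue = set(), deque(adj.get(start, []))
    while queue:
        node = queue.popleft()
        if node in seen:
            continue
        seen.add(node)
        queue.extend(adj.get(node, []))
    seen.discard(start)
    return seen


def brute_force_search(atags, edges, q):
    """Linear scan applying the documented match predicate and ranking."""
    rows = []
    for pos, a in enumerate(atags):
        direct = set(a.tag_uris())
        expanded = set(direct)
        for u in direct:
            expanded |= bfs_ancestors(edges, u)
        fields = [a.text] + [t.preferred_label for t in a.tags]
        if q.keyword and q.keyword.strip():
            kw = q.keyword.strip().lower()
            if not any(kw in f.lower() for f in fields):
                continue
            relevance = sum(f.lower().count(kw) for f in fields)
        else:
            relevance = 0
        if not (q.selected_tags <= direct and q.selected_broader <= expanded):
            continue
        rows.append((-relevance, pos, a, direct, expanded))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def random_world(rng, n_entities=60, n_atags=80):
    uris = [f"http://example.org/e/{i}" for i in range(n_entities)]
    entities = [OntologyEntity(u, f"entity {i}")
                for i, u in enumerate(uris)]
    g = OntologyGraph()
    for e in entities:
        g.add_entity(e)
    edges = set()
    for i in range(n_entities):
        for _ in range(rng.randint(0, 3)):
            j = rng.randrange(i + 1, n_entities + 1)
            if j < n_entities:
                edges.add((uris[i], uris[j]))  # i -> j with i<j: acyclic
    for a, b in edges:
        g.add_broader_edge(a, b)
    words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    collection = AtagCollection(base_uri=BASE)
    for i in range(n_atags):
        text = f"s{i} " + " ".join(rng.choices(words, k=rng.randint(2, 6)))
        tags = rng.sample(entities, rng.randint(0, 4))
        collection.atags.append(make_atag(text, tags, base_uri=BASE))
    return collection, g, edges, words


def random_query(rng, uris, words):
    return FacetQuery(
        keyword=rng.choice([None, ""] + words),
        selected_tags=frozenset(rng.sample(uris, rng.randint(0, 2))),
        selected_broader=frozenset(rng.sample(uris, rng.randint(0, 2))))


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

class TestBroaderClosure:
    def test_chain_leaf_to_root(self):
        g = OntologyGraph()
        g.add_broader_edge("http://x/leaf", "http://x/mid")
        g.add_broader_edge("http://x/mid", "http://x/root")
        assert broader_closure("http://x/leaf", g) == {
            "http://x/mid", "http://x/root"}
        assert broader_closure("http://x/root", g) == set()

    def test_unknown_uri_has_empty_closure(self):
        assert broader_closure("http://x/nowhere", OntologyGraph()) == set()

    def test_random_dag_matches_bfs_oracle(self):
        rng = random.Random(42)
        _c, g, edges, _w = random_world(rng, n_entities=120, n_atags=1)
        uris = sorted({u for e in edges for u in e})
        for u in rng.sample(uris, min(30, len(uris))):
            assert broader_closure(u, g) == bfs_ancestors(edges, u)

    def test_cycle_detected_and_closure_terminates(self, caplog):
        g = OntologyGraph()
        g.add_broader_edge("http://x/a", "http://x/b")
        g.add_broader_edge("http://x/b", "http://x/a")
        g.add_broader_edge("http://x/b", "http://x/c")
        with caplog.at_level("WARNING"):
            cycles = g.check_cycles()
        assert cycles and any("cycle" in r.message for r in caplog.records)
        # members of the cycle see each other (not themselves) plus c
        assert broader_closure("http://x/a", g) == {"http://x/b", "http://x/c"}


# ---------------------------------------------------------------------------
# indexing and search
# ---------------------------------------------------------------------------

class TestIndexAndSearch:
    def test_empty_collection_answers_empty(self):
        idx = build_index(AtagCollection(base_uri=BASE), OntologyGraph())
        r = search(idx, FacetQuery(keyword="anything"))
        assert r.atags == [] and r.tag_facet == [] and r.broader_facet == []

    def test_expanded_set_is_union_of_closures(self):
        g = OntologyGraph()
        g.add_broader_edge("http://x/leaf", "http://x/mid")
        g.add_broader_edge("http://x/mid", "http://x/root")
        a = make_atag("leafy statement",
                      [OntologyEntity("http://x/leaf", "leaf")],
                      base_uri=BASE)
        idx = build_index(AtagCollection(base_uri=BASE, atags=[a]), g)
        assert idx.expanded[0] == {"http://x/leaf", "http://x/mid",
                                   "http://x/root"}

    def test_empty_query_returns_everything_with_store_wide_facets(self):
        rng = random.Random(0)
        c, g, _e, _w = random_world(rng, n_entities=20, n_atags=15)
        r = search(build_index(c, g), FacetQuery())
        assert r.atags == c.atags
        for _ent, n in r.tag_facet + r.broader_facet:
            assert 1 <= n <= len(r.atags)

    @pytest.mark.parametrize("seed", range(5))
    def test_search_equals_brute_force_scan(self, seed):
        rng = random.Random(seed)
        c, g, edges, words = random_world(rng)
        idx = build_index(c, g)
        uris = [e.uri for e in g.entities.values()]
        for _ in range(20):
            q = random_query(rng, uris, words)
            expected = brute_force_search(c.atags, edges, q)
            got = search(idx, q)
            assert [a.id_uri for a in got.atags] == [
                r[2].id_uri for r in expected]
            # facet count conservation against the brute-force sets
            tag_counts = {}
            broader_counts = {}
            for _neg, _pos, _a, direct, expanded in expected:
                for u in direct:
                    tag_counts[u] = tag_counts.get(u, 0) + 1
                for u in expanded - direct:
                    broader_counts[u] = broader_counts.get(u, 0) + 1
            assert {e.uri: n for e, n in got.tag_facet} == tag_counts
            assert {e.uri: n for e, n in got.broader_facet} == broader_counts

    def test_relevance_ranks_by_keyword_occurrences(self):
        g = OntologyGraph()
        a1 = make_atag("alpha beta", [], base_uri=BASE)
        a2 = make_atag("alpha alpha alpha", [], base_uri=BASE)
        idx = build_index(AtagCollection(base_uri=BASE, atags=[a1, a2]), g)
        r = search(idx, FacetQuery(keyword="alpha"))
        assert [a.id_uri for a in r.atags] == [a2.id_uri, a1.id_uri]

    def test_narrowing_monotonic_and_unfocus_reversible(self):
        rng = random.Random(7)
        c, g, _e, words = random_world(rng)
        idx = build_index(c, g)
        uris = [e.uri for e in g.entities.values()]
        for _ in range(50):
            q = random_query(rng, uris, words)
            base_ids = [a.id_uri for a in search(idx, q).atags]
            extra = rng.choice(uris)
            narrowed = rng.choice([q.with_tag(extra), q.with_broader(extra)])
            narrowed_ids = [a.id_uri for a in search(idx, narrowed).atags]
            assert set(narrowed_ids) <= set(base_ids)
            assert [a.id_uri for a in search(idx, q).atags] == base_ids


class TestFocusEntity:
    def test_focus_returns_only_atags_carrying_the_tag(self):
        rng = random.Random(3)
        c, g, _e, _w = random_world(rng)
        idx = build_index(c, g)
        for uri in list(g.entities)[:10]:
            r = focus_entity(idx, uri)
            for a in r.atags:
                assert uri in a.tag_uris()

    def test_focus_unknown_uri_is_empty(self):
        c, g = gen_drug_store(0)
        r = focus_entity(build_index(c, g), "http://example.org/nothing")
        assert r.atags == []

    def test_celecoxib_focus_shows_pyrazole_as_broader(self):
        c, g = gen_drug_store(0)
        r = focus_entity(build_index(c, g), DBP + "Celecoxib")
        assert r.atags
        assert DBP + "Pyrazole" in r.facet_uris("broader")


class TestOntologyIO:
    def test_turtle_roundtrip_preserves_edges_and_labels(self):
        _c, g = gen_drug_store(0)
        g2 = load_ontology_turtle(ontology_to_turtle(g))
        assert g2.broader_edges == g.broader_edges
        assert {u: e.preferred_label for u, e in g2.entities.items()} == {
            u: e.preferred_label for u, e in g.entities.items()}

    def test_subclass_and_preflabel_also_recognized(self):
        ttl = """
        @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
        @prefix skos: <http://www.w3.org/2004/02/skos/core#> .
        <http://x/Celecoxib> rdfs:subClassOf <http://x/Pyrazole> ;
            skos:prefLabel "celecoxib" .
        """
        g = load_ontology_turtle(ttl)
        assert ("http://x/Celecoxib", "http://x/Pyrazole") in g.broader_edges
        assert g.entities["http://x/Celecoxib"].preferred_label == "celecoxib"

    def test_edge_list_loader(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        labels = tmp_path / "labels.tsv"
        edges.write_text("http://x/a\thttp://x/b\n# comment\n")
        labels.write_text("http://x/a\talpha\n")
        g = load_ontology_edge_lists(edges, labels)
        assert g.broader_edges == {("http://x/a", "http://x/b")}
        assert g.entities["http://x/a"].preferred_label == "alpha"
        assert g.entities["http://x/b"].preferred_label == "b"  # auto-registered
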