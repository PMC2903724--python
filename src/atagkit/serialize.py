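"""RDF serialization of aTags: XHTML+RDFa and Turtle, with round-tripping.

aTags are normally carried as short snippets of HTML with embedded RDF so
that a single document serves both human readers and machines, and so
that copying a snippet between pages carries its statements along.  The
property vocabulary is SIOC plus Dublin Core terms, centralized in the
constants below so it can be re-pointed in one place:

========================  =========================================
aTag aspect               RDF property
========================  =========================================
the aTag itself           ``rdf:type sioc:Item``
assertion snippet text    ``sioc:content`` (plain literal)
each entity tag           ``sioc:topic`` (object = entity IRI)
entity display label      ``rdfs:label`` on the entity
source document           ``dcterms:source``
creation timestamp        ``dcterms:created`` (``xsd:dateTime``)
========================  =========================================

The HTML dialect is the RDFa 1.1 attribute set (``prefix``, ``about``,
``typeof``, ``property``, ``href``, ``content``) on XHTML.  Every emitted
fragment declares its own prefix map, so fragments stay self-contained
when copied and pasted between documents.  Turtle reading and writing is
delegated to rdflib; the RDFa subset processor here implements exactly
the dialect this module emits.
"""

from __future__ import annotations

import logging
from datetime import datetime, timezone
from typing import Iterable, Mapping, Optional

from lxml import etree, html as lxml_html
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .model import (
    Atag,
    AtagCollection,
    OntologyEntity,
    ValidationError,
    guess_vocabulary,
    validate_atag,
)

__all__ = [
    "SIOC",
    "DCTERMS",
    "DEFAULT_PREFIXES",
    "atag_to_rdfa",
    "atags_to_rdfa_page",
    "rdfa_to_atags",
    "rdfa_to_triples",
    "atags_to_turtle",
    "turtle_to_atags",
    "turtle_to_triples",
    "atag_triples",
]

logger = logging.getLogger(__name__)

SIOC = Namespace("http://rdfs.org/sioc/ns#")
DCTERMS = Namespace("http://purl.org/dc/terms/")

#: Prefixes declared on every emitted document.  Callers may extend this
#: map (e.g. with ``dbpedia`` or ``mesh``) but sioc/dcterms/rdfs are
#: always present because the aTag properties live there.
DEFAULT_PREFIXES: dict[str, str] = {
    "sioc": str(SIOC),
    "dcterms": str(DCTERMS),
    "rdfs": str(RDFS),
}


class RdfaParseError(ValueError):
    """Raised when an input document cannot be parsed as markup."""


def _merged_prefixes(prefix_map: Optional[Mapping[str, str]]) -> dict[str, str]:
    merged = dict(DEFAULT_PREFIXES)
    if prefix_map:
        merged.update(prefix_map)
    return merged


def _prefix_attr(prefixes: Mapping[str, str]) -> str:
    return " ".join(f"{p}: {iri}" for p, iri in sorted(prefixes.items()))


def _curie(uri: str, prefixes: Mapping[str, str]) -> str:
    """Compress *uri* to a CURIE under the longest matching prefix, else
    return it unchanged (RDFa accepts absolute IRIs where CURIEs go)."""
    best = ""
    best_prefix = None
    for p, ns in prefixes.items():
        if uri.startswith(ns) and len(ns) > len(best):
            best, best_prefix = ns, p
    if best_prefix is not None and len(uri) > len(best):
        return f"{best_prefix}:{uri[len(best):]}"
    return uri


def _expand(term: str, prefixes: Mapping[str, str]) -> str:
    """Expand a CURIE against *prefixes*; absolute IRIs pass through."""
    if ":" in term:
        p, rest = term.split(":", 1)
        if p in prefixes and not rest.startswith("//"):
            return prefixes[p] + rest
    return term


def _format_created(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).isoformat()


def _parse_created(value: str) -> Optional[datetime]:
    try:
        return datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError:
        logger.warning("unparseable dcterms:created value %r ignored", value)
        return None


# ---------------------------------------------------------------------------
# RDFa emission
# ---------------------------------------------------------------------------

def _atag_element(a: Atag, prefixes: Mapping[str, str], *, declare_prefixes: bool,
                  lang: Optional[str] = None) -> etree._Element:
    problems = validate_atag(a)
    if problems:
        raise ValidationError("cannot serialize invalid aTag: " + "; ".join(problems))
    div = etree.Element("div")
    div.set("class", "atag")
    if declare_prefixes:
        div.set("prefix", _prefix_attr(prefixes))
    div.set("about", a.id_uri)
    div.set("typeof", _curie(str(SIOC.Item), prefixes))
    span = etree.SubElement(div, "span")
    span.set("class", "atag-text")
    span.set("property", _curie(str(SIOC.content), prefixes))
    if lang:
        span.set("lang", lang)
    span.text = a.text
    if a.tags:
        tags_span = etree.SubElement(div, "span")
        tags_span.set("class", "atag-tags")
        tags_span.text = " ["
        for i, ent in enumerate(a.tags):
            anchor = etree.SubElement(tags_span, "a")
            anchor.set("property", _curie(str(SIOC.topic), prefixes))
            anchor.set("href", ent.uri)
            label = etree.SubElement(anchor, "span")
            label.set("about", ent.uri)
            label.set("property", _curie(str(RDFS.label), prefixes))
            label.text = ent.preferred_label
            anchor.tail = ", " if i < len(a.tags) - 1 else "]"
    if a.provenance_uri is not None:
        src = etree.SubElement(div, "a")
        src.set("class", "atag-source")
        src.set("property", _curie(str(DCTERMS.source), prefixes))
        src.set("href", a.provenance_uri)
        src.text = "source"
    if a.created is not None:
        created = etree.SubElement(div, "span")
        created.set("property", _curie(str(DCTERMS.created), prefixes))
        created.set("datatype", _curie(str(XSD.dateTime), prefixes))
        created.set("content", _format_created(a.created))
    return div


def atag_to_rdfa(a: Atag, prefix_map: Optional[Mapping[str, str]] = None,
                 *, lang: Optional[str] = None) -> str:
    """Serialize one aTag as a self-contained XHTML+RDFa ``<div>`` fragment.

    The fragment carries its own ``prefix`` declaration so its embedded
    statements survive copy-and-paste into any other document.  Output is
    deterministic: the same aTag and prefix map give byte-identical HTML.
    """
    prefixes = _merged_prefixes(prefix_map)
    el = _atag_element(a, prefixes, declare_prefixes=True, lang=lang)
    return etree.tostring(el, encoding="unicode", method="xml")


def atags_to_rdfa_page(c: AtagCollection,
                       prefix_map: Optional[Mapping[str, str]] = None,
                       *, title: str = "aTags",
                       lang: Optional[str] = None) -> str:
    """Serialize a collection as a standalone XHTML page.

    Prefixes are declared once on the root element; each aTag becomes one
    ``div.atag`` in collection order.
    """
    problems = c.violations()
    if problems:
        raise ValidationError("cannot serialize invalid collection: " + "; ".join(problems))
    prefixes = _merged_prefixes(prefix_map)
    root = etree.Element("html", nsmap={None: "http://www.w3.org/1999/xhtml"})
    root.set("prefix", _prefix_attr(prefixes))
    head = etree.SubElement(root, "head")
    t = etree.SubElement(head, "title")
    t.text = title
    body = etree.SubElement(root, "body")
    for a in c.atags:
        body.append(_atag_element(a, prefixes, declare_prefixes=False, lang=lang))
    doc = etree.tostring(root, encoding="unicode", method="xml")
    return '<?xml version="1.0" encoding="utf-8"?>\n' + doc + "\n"


# ---------------------------------------------------------------------------
# RDFa parsing (subset processor for the dialect emitted above)
# ---------------------------------------------------------------------------

def _parse_prefix_attr(value: str) -> dict[str, str]:
    tokens = value.split()
    out: dict[str, str] = {}
    for i in range(0, len(tokens) - 1, 2):
        name = tokens[i]
        if name.endswith(":"):
            out[name[:-1]] = tokens[i + 1]
    return out


def _parse_markup(text: str) -> etree._Element:
    if not text or not text.strip():
        raise RdfaParseError("empty document")
    parser = lxml_html.HTMLParser(encoding="utf-8")
    try:
        return lxml_html.document_fromstring(text.encode("utf-8"), parser=parser)
    except (etree.ParserError, ValueError) as exc:
        raise RdfaParseError(f"cannot parse markup: {exc}") from exc


def _text_content(el: etree._Element) -> str:
    return "".join(el.itertext())


_XHTML_NS = "{http://www.w3.org/1999/xhtml}"


def _local_name(el: etree._Element) -> str:
    tag = el.tag
    if isinstance(tag, str):
        return tag.removeprefix(_XHTML_NS)
    return ""


def _walk_rdfa(el, prefixes, subject, visit):
    """Depth-first traversal tracking the prefix environment and subject.

    *visit* is called for every element as ``visit(el, prefixes, subject)``
    and returns the subject its children inherit (or ``None`` to prune the
    subtree).
    """
    attr = el.get("prefix")
    if attr:
        prefixes = {**prefixes, **_parse_prefix_attr(attr)}
    child_subject = visit(el, prefixes, subject)
    if child_subject is _PRUNE:
        return
    for child in el:
        _walk_rdfa(child, prefixes, child_subject, visit)


_PRUNE = object()


def rdfa_to_atags(doc: str) -> list[Atag]:
    """Extract every aTag from an XHTML+RDFa document or fragment.

    Any element typed ``sioc:Item`` that carries a ``sioc:content``
    annotation yields one :class:`Atag`; unknown extra markup is ignored.
    Tag order follows document order.  A ``sioc:Item`` without content is
    skipped with a warning.

    Raises
    ------
    RdfaParseError
        If the input cannot be parsed as markup at all.
    """
    root = _parse_markup(doc)
    atags: list[Atag] = []

    def handle_item(item_el, prefixes):
        subject = item_el.get("about") or item_el.get("resource") or ""
        text: Optional[str] = None
        entities: list[OntologyEntity] = []
        provenance: Optional[str] = None
        created: Optional[datetime] = None

        def visit(el, pfx, _subj):
            nonlocal text, provenance, created
            if el is not item_el and _is_item(el, pfx):
                return _PRUNE  # nested items handled by the outer scan
            prop = el.get("property")
            if not prop:
                return None
            expanded = {_expand(p, pfx) for p in prop.split()}
            if str(SIOC.content) in expanded and text is None:
                text = el.get("content") or _text_content(el)
            if str(SIOC.topic) in expanded:
                href = el.get("href") or el.get("resource")
                if href:
                    label = _text_content(el).strip() or _label_from_uri(href)
                    entities.append(OntologyEntity(
                        uri=href, preferred_label=label,
                        source_vocabulary=guess_vocabulary(href)))
            if str(DCTERMS.source) in expanded:
                href = el.get("href") or el.get("resource")
                if href:
                    provenance = href
            if str(DCTERMS.created) in expanded and el.get("content"):
                created = _parse_created(el.get("content"))
            return None

        _walk_rdfa(item_el, prefixes, subject, visit)
        if text is None or not text.strip():
            logger.warning("sioc:Item %s lacks sioc:content; skipped", subject or "<no id>")
            return
        seen: set[str] = set()
        uniq = tuple(e for e in entities if not (e.uri in seen or seen.add(e.uri)))
        atags.append(Atag(id_uri=subject, text=text, tags=uniq,
                          provenance_uri=provenance, created=created))

    def scan(el, prefixes, _subject):
        if _is_item(el, prefixes):
            handle_item(el, prefixes)
            return _PRUNE
        return None

    _walk_rdfa(root, {}, None, scan)
    return atags


def _is_item(el, prefixes) -> bool:
    typeof = el.get("typeof")
    if not typeof:
        return False
    return str(SIOC.Item) in {_expand(t, prefixes) for t in typeof.split()}


def _label_from_uri(uri: str) -> str:
    tail = uri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return tail.replace("_", " ") or uri


def rdfa_to_triples(doc: str) -> frozenset:
    """Extract the full embedded triple set of an RDFa document.

    Returns a frozen set of ``(subject, predicate, object)`` triples using
    rdflib terms, directly comparable with the triples of a Turtle
    serialization parsed by rdflib.
    """
    root = _parse_markup(doc)
    triples: set = set()

    def visit(el, prefixes, subject):
        about = el.get("about")
        if about is not None:
            subject = about
        typeof = el.get("typeof")
        if typeof and subject:
            for t in typeof.split():
                triples.add((URIRef(subject), RDF.type, URIRef(_expand(t, prefixes))))
        prop = el.get("property")
        if prop and subject:
            href = el.get("href") or el.get("resource")
            for p in prop.split():
                pred = URIRef(_expand(p, prefixes))
                if href is not None:
                    triples.add((URIRef(subject), pred, URIRef(href)))
                elif el.get("content") is not None:
                    dt = el.get("datatype")
                    obj = Literal(el.get("content"),
                                  datatype=URIRef(_expand(dt, prefixes)) if dt else None)
                    triples.add((URIRef(subject), pred, obj))
                else:
                    lang = el.get("lang") or el.get(
                        "{http://www.w3.org/XML/1998/namespace}lang")
                    triples.add((URIRef(subject), pred,
                                 Literal(_text_content(el), lang=lang)))
        return subject

    _walk_rdfa(root, {}, None, visit)
    return frozenset(triples)


# ---------------------------------------------------------------------------
# Turtle (via rdflib)
# ---------------------------------------------------------------------------

def atag_triples(a: Atag, *, lang: Optional[str] = None) -> list[tuple]:
    """The RDF triples asserted by one aTag, as rdflib terms."""
    s = URIRef(a.id_uri)
    out: list[tuple] = [(s, RDF.type, SIOC.Item),
                        (s, SIOC.content, Literal(a.text, lang=lang))]
    for ent in a.tags:
        out.append((s, SIOC.topic, URIRef(ent.uri)))
        out.append((URIRef(ent.uri), RDFS.label, Literal(ent.preferred_label)))
    if a.provenance_uri is not None:
        out.append((s, DCTERMS.source, URIRef(a.provenance_uri)))
    if a.created is not None:
        out.append((s, DCTERMS.created,
                    Literal(_format_created(a.created), datatype=XSD.dateTime)))
    return out


def atags_to_turtle(c: AtagCollection,
                    prefix_map: Optional[Mapping[str, str]] = None,
                    *, lang: Optional[str] = None) -> str:
    """Serialize a collection as Turtle.

    Expresses exactly the same triple set as the RDFa serialization of the
    same collection.  Prefixes for sioc, dcterms and rdfs are always
    declared; *prefix_map* adds further vocabularies.
    """
    problems = c.violations()
    if problems:
        raise ValidationError("cannot serialize invalid collection: " + "; ".join(problems))
    g = Graph(bind_namespaces="none")
    for p, ns in sorted(_merged_prefixes(prefix_map).items()):
        g.bind(p, Namespace(ns), replace=True)
    for a in c.atags:
        for triple in atag_triples(a, lang=lang):
            g.add(triple)
    if len(g) == 0:
        # rdflib elides unused prefixes; an empty store is still a valid
        # document consisting of the prefix declarations alone
        return "".join(f"@prefix {p}: <{ns}> .\n"
                       for p, ns in sorted(_merged_prefixes(prefix_map).items()))
    return g.serialize(format="turtle")


def turtle_to_triples(ttl: str) -> frozenset:
    """Parse Turtle text into a frozen set of rdflib triples."""
    g = Graph()
    g.parse(data=ttl, format="turtle")
    return frozenset(g)


def turtle_to_atags(ttl: str, base_uri: Optional[str] = None) -> AtagCollection:
    """Load an aTag collection from Turtle text.

    Inverse of :func:`atags_to_turtle` on its image, up to ordering:
    Turtle is set-oriented, so aTags come back sorted by identifier and
    tags sorted by entity URI.  ``sioc:Item`` subjects without a
    ``sioc:content`` literal are skipped with a warning.

    Raises a parse error (with line information from rdflib) on malformed
    Turtle.
    """
    g = Graph()
    g.parse(data=ttl, format="turtle")
    atags: list[Atag] = []
    for s in sorted(g.subjects(RDF.type, SIOC.Item), key=str):
        text = g.value(s, SIOC.content)
        if text is None or not str(text).strip():
            logger.warning("sioc:Item %s lacks sioc:content; skipped", s)
            continue
        entities = []
        for topic in sorted(g.objects(s, SIOC.topic), key=str):
            label = g.value(topic, RDFS.label)
            entities.append(OntologyEntity(
                uri=str(topic),
                preferred_label=str(label) if label is not None else _label_from_uri(str(topic)),
                source_vocabulary=guess_vocabulary(str(topic))))
        prov = g.value(s, DCTERMS.source)
        created_lit = g.value(s, DCTERMS.created)
        created = _parse_created(str(created_lit)) if created_lit is not None else None
        atags.append(Atag(id_uri=str(s), text=str(text), tags=tuple(entities),
                          provenance_uri=str(prov) if prov is not None else None,
                          created=created))
    if base_uri is None:
        base_uri = atags[0].id_uri.split("#", 1)[0] if atags else "http://example.org/atags"
    return AtagCollection(base_uri=base_uri, atags=atags)
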