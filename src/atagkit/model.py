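"""Core data model for aTags (associative tags).

An aTag is a short piece of human-readable text -- typically a single
scientific assertion -- annotated with a set of entities drawn from
ontologies and taxonomies (OBO ontologies, DBpedia, MeSH, ...).  No
relations between the entities are asserted: the representation trades
expressivity for simplicity and mergeability.

This module defines the in-memory types (:class:`OntologyEntity`,
:class:`Atag`, :class:`AtagCollection`), the validating constructor
:func:`make_atag`, and a deterministic identifier-minting scheme
(:func:`mint_atag_uri`) so that the same assertion with the same tag set
always receives the same IRI.
"""

from __future__ import annotations

import hashlib
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

__all__ = [
    "ValidationError",
    "OntologyEntity",
    "Atag",
    "AtagCollection",
    "is_valid_iri",
    "guess_vocabulary",
    "normalize_text",
    "mint_atag_uri",
    "make_atag",
    "validate_atag",
]


class ValidationError(ValueError):
    """Raised when input to a constructor violates an aTag invariant."""


# Absolute IRI: scheme, then a non-empty remainder free of whitespace and
# characters excluded by RFC 3987.  Deliberately permissive beyond that --
# tags come from many vocabularies and we only need to reject obvious junk.
_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:[^\s<>\"{}|\\^`]+$")

_WS_RE = re.compile(r"\s+")


def is_valid_iri(value: str) -> bool:
    """True if *value* is a syntactically plausible absolute IRI."""
    return isinstance(value, str) and bool(_IRI_RE.match(value))


#: Namespace prefixes used to classify entity URIs into source vocabularies.
#: Checked in order; first match wins.
VOCABULARY_NAMESPACES: tuple[tuple[str, str], ...] = (
    ("http://dbpedia.org/", "dbpedia"),
    ("http://purl.obolibrary.org/obo/", "obo"),
    ("http://purl.org/obo/", "obo"),
    ("http://id.nlm.nih.gov/mesh/", "mesh"),
)


def guess_vocabulary(uri: str) -> str:
    """Classify an entity URI into a source-vocabulary tag by namespace.

    Returns ``"other"`` for namespaces not listed in
    :data:`VOCABULARY_NAMESPACES`.  Used when reading aTags back from RDF,
    where the vocabulary tag is not carried explicitly.
    """
    for prefix, vocab in VOCABULARY_NAMESPACES:
        if uri.startswith(prefix):
            return vocab
    return "other"


@dataclass(frozen=True)
class OntologyEntity:
    """A labeled entity from an ontology or taxonomy, used as a tag.

    Parameters
    ----------
    uri:
        Absolute IRI identifying the entity (e.g. a DBpedia resource or an
        OBO class).
    preferred_label:
        Human-readable label shown wherever the tag is displayed.
    source_vocabulary:
        Short tag naming the vocabulary the entity comes from
        (``"dbpedia"``, ``"obo"``, ``"mesh"``, ``"other"``).
    """

    uri: str
    preferred_label: str
    source_vocabulary: str = "other"

    def violations(self) -> list[str]:
        out = []
        if not is_valid_iri(self.uri):
            out.append(f"entity uri is not a valid absolute IRI: {self.uri!r}")
        if not str(self.preferred_label).strip():
            out.append(f"entity preferred_label is empty (uri={self.uri!r})")
        return out


@dataclass(frozen=True)
class Atag:
    """One associative tag: an assertion snippet plus its entity tags.

    ``tags`` is an ordered, duplicate-free (by URI) tuple; insertion order
    is preserved for display.  The tag set may be empty and its size is
    unbounded.
    """

    id_uri: str
    text: str
    tags: tuple[OntologyEntity, ...] = ()
    provenance_uri: Optional[str] = None
    created: Optional[datetime] = None

    def tag_uris(self) -> list[str]:
        return [t.uri for t in self.tags]

    def canonical(self) -> "Atag":
        """This aTag with tags sorted by URI, for order-insensitive
        comparison (set-oriented serializations do not preserve tag
        insertion order)."""
        from dataclasses import replace
        return replace(self, tags=tuple(sorted(self.tags, key=lambda t: t.uri)))


@dataclass
class AtagCollection:
    """An ordered collection of aTags sharing a minting base IRI."""

    base_uri: str
    atags: list[Atag] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.atags)

    def __iter__(self):
        return iter(self.atags)

    def violations(self) -> list[str]:
        out = []
        if not is_valid_iri(self.base_uri):
            out.append(f"base_uri is not a valid absolute IRI: {self.base_uri!r}")
        seen: dict[str, int] = {}
        for i, a in enumerate(self.atags):
            out.extend(validate_atag(a))
            if a.id_uri in seen:
                out.append(
                    f"duplicate id_uri at positions {seen[a.id_uri]} and {i}: {a.id_uri}"
                )
            else:
                seen[a.id_uri] = i
        return out


def normalize_text(text: str) -> str:
    """Canonical text form used for identifier minting.

    Unicode NFC, internal whitespace runs collapsed to single spaces,
    leading/trailing whitespace trimmed.  Display text is never modified;
    this form exists only so that cosmetic whitespace differences do not
    change a minted identifier.
    """
    return _WS_RE.sub(" ", unicodedata.normalize("NFC", text)).strip()


def mint_atag_uri(text: str, tag_uris: Sequence[str], base_uri: str) -> str:
    """Mint a deterministic IRI for an aTag.

    The identifier is ``base_uri + "#atag-" + h`` where *h* is the first 12
    hex characters of the SHA-256 digest of the normalized text, a newline,
    and the newline-joined *sorted* tag URIs.  Pure function: identical
    inputs (up to tag order and cosmetic whitespace) give identical IRIs.
    """
    if not is_valid_iri(base_uri):
        raise ValidationError(f"base_uri is not a valid absolute IRI: {base_uri!r}")
    payload = normalize_text(text) + "\n" + "\n".join(sorted(tag_uris))
    digest = hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]
    return f"{base_uri}#atag-{digest}"


def dedupe_entities(entities: Iterable[OntologyEntity]) -> tuple[OntologyEntity, ...]:
    """Collapse duplicate URIs, keeping first occurrence (first label wins)."""
    seen: set[str] = set()
    out: list[OntologyEntity] = []
    for e in entities:
        if e.uri not in seen:
            seen.add(e.uri)
            out.append(e)
    return tuple(out)


def make_atag(
    text: str,
    entities: Sequence[OntologyEntity] = (),
    provenance_uri: Optional[str] = None,
    *,
    base_uri: str,
    created: Optional[datetime] = None,
) -> Atag:
    """Construct a validated aTag with a deterministically minted identifier.

    This is the programmatic equivalent of highlighting a statement and
    tagging it: *text* is the highlighted assertion, *entities* the chosen
    ontology tags.  Duplicate entities (same URI) collapse silently to the
    first occurrence.

    Raises
    ------
    ValidationError
        If *text* is empty after trimming, or any IRI involved is malformed.
    """
    if not text or not text.strip():
        raise ValidationError("aTag text must be non-empty after trimming")
    for e in entities:
        problems = e.violations()
        if problems:
            raise ValidationError("; ".join(problems))
    if provenance_uri is not None and not is_valid_iri(provenance_uri):
        raise ValidationError(
            f"provenance_uri is not a valid absolute IRI: {provenance_uri!r}"
        )
    if created is not None and created.tzinfo is None:
        created = created.replace(tzinfo=timezone.utc)
    tags = dedupe_entities(entities)
    id_uri = mint_atag_uri(text, [t.uri for t in tags], base_uri)
    return Atag(
        id_uri=id_uri,
        text=text,
        tags=tags,
        provenance_uri=provenance_uri,
        created=created,
    )


def validate_atag(a: Atag) -> list[str]:
    """Report (not raise) every invariant violation of *a*.

    Returns an empty list iff *a* is well-formed.  Each message names the
    offending field, so callers can surface precise diagnostics.
    """
    out: list[str] = []
    if not is_valid_iri(a.id_uri):
        out.append(f"id_uri is not a valid absolute IRI: {a.id_uri!r}")
    if not a.text or not a.text.strip():
        out.append("text is empty after trimming")
    seen: set[str] = set()
    for e in a.tags:
        for msg in e.violations():
            out.append(f"tags: {msg}")
        if e.uri in seen:
            out.append(f"tags: duplicate entity uri {e.uri!r}")
        seen.add(e.uri)
    if a.provenance_uri is not None and not is_valid_iri(a.provenance_uri):
        out.append(
            f"provenance_uri is not a valid absolute IRI: {a.provenance_uri!r}"
        )
    return out
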