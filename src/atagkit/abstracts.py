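"""Mining aTags from structured abstracts.

A sizeable fraction of biomedical abstracts are *structured*: the
narrative is delineated by explicit ALL-CAPS section headers such as
``INTRODUCTION:``, ``METHODS:``, ``RESULTS:``, ``CONCLUSIONS:``.  The
conclusion section of such an abstract is a nearly self-contained key
assertion -- far less noisy than introduction or results sentences --
and makes a good aTag once two problems are fixed:

1. abstracts define local abbreviations early ("Seasonal affective
   disorder (SAD) is common in ...") and then use the opaque short form
   in the conclusion ("This study shows that SAD is effectively treated
   with ...").  We detect definitions with the Schwartz & Hearst
   candidate/long-form matching rule and expand short forms in the
   extracted conclusion, making it intelligible in isolation;
2. the assertion needs machine-readable tags.  The indexing descriptors
   (MeSH terms) attached to the record supply them.

This module works on local abstract records (identifier, title, abstract
text, MeSH descriptor list); it performs no live retrieval.  The query
used to assemble a conclusion-section corpus from PubMed is shipped as
documentation in :data:`PUBMED_CONCLUSION_QUERY`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .model import Atag, OntologyEntity, guess_vocabulary, make_atag

__all__ = [
    "AbstractRecord",
    "StructuredSection",
    "AbbreviationDefinition",
    "DEFAULT_HEADER_VOCABULARY",
    "UNSTRUCTURED",
    "MESH_NAMESPACE",
    "PUBMED_URI_TEMPLATE",
    "PUBMED_CONCLUSION_QUERY",
    "segment_abstract",
    "find_abbreviations",
    "expand_abbreviations",
    "extract_conclusion_atags",
    "records_from_jsonl",
    "records_to_jsonl",
]

logger = logging.getLogger(__name__)

UNSTRUCTURED = "UNSTRUCTURED"

#: Default header vocabulary, mapping the raw header (without the trailing
#: colon) to a canonical section label.  Matched case-sensitively, ALL-CAPS
#: followed by ``:`` only.  Covers common MEDLINE structured-abstract
#: practice; override per call for other corpora.
DEFAULT_HEADER_VOCABULARY: dict[str, str] = {
    "BACKGROUND": "BACKGROUND",
    "INTRODUCTION": "INTRODUCTION",
    "OBJECTIVE": "OBJECTIVES",
    "OBJECTIVES": "OBJECTIVES",
    "AIM": "OBJECTIVES",
    "AIMS": "OBJECTIVES",
    "METHODS": "METHODS",
    "MATERIALS AND METHODS": "METHODS",
    "RESULTS": "RESULTS",
    "FINDINGS": "RESULTS",
    "DISCUSSION": "DISCUSSION",
    "CONCLUSION": "CONCLUSIONS",
    "CONCLUSIONS": "CONCLUSIONS",
    "INTERPRETATION": "CONCLUSIONS",
}

MESH_NAMESPACE = "http://id.nlm.nih.gov/mesh/"
PUBMED_URI_TEMPLATE = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"

#: The retrieval query used for the original emotion/cognition trial
#: corpus.  Kept as documentation only; this toolkit reads local records.
PUBMED_CONCLUSION_QUERY = (
    '("conclusion"[Title/Abstract] OR "conclusions"[Title/Abstract]) AND '
    '(antidepressant OR "Emotions"[Mesh] OR "Behavioral Symptoms"[Mesh] OR '
    '"Mood Disorders"[Mesh])'
)


@dataclass(frozen=True)
class AbstractRecord:
    """One abstract record: identifier, title, text and MeSH descriptors.

    ``mesh_terms`` is a list of ``(descriptor_ui, label)`` pairs.
    ``abstract_text`` may be empty; such records yield no aTag.
    """

    pmid: str
    title: str
    abstract_text: str
    mesh_terms: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class StructuredSection:
    """A header-delimited slice of an abstract.

    ``span`` is the 0-based half-open character range in the original
    abstract covered by ``raw_header + text``; concatenating all sections
    in order reconstructs the abstract exactly.
    """

    label: str
    raw_header: str
    text: str
    span: tuple[int, int]


@dataclass(frozen=True)
class AbbreviationDefinition:
    """A locally defined abbreviation: short form, long form, and the
    0-based half-open span of the parenthesized short form (including the
    parentheses)."""

    short_form: str
    long_form: str
    definition_span: tuple[int, int]


def _compile_header_re(vocabulary: Mapping[str, str]) -> re.Pattern:
    # longest-first so "MATERIALS AND METHODS:" wins over "METHODS:"
    alts = sorted(vocabulary, key=len, reverse=True)
    pattern = r"(?<![A-Za-z])(?:" + "|".join(re.escape(h) for h in alts) + r"):"
    return re.compile(pattern)


def _normalize_vocabulary(
    header_vocabulary: Union[Mapping[str, str], Sequence[str], None],
) -> dict[str, str]:
    if header_vocabulary is None:
        return DEFAULT_HEADER_VOCABULARY
    if isinstance(header_vocabulary, Mapping):
        return dict(header_vocabulary)
    return {h: DEFAULT_HEADER_VOCABULARY.get(h, h) for h in header_vocabulary}


def segment_abstract(
    abstract_text: str,
    header_vocabulary: Union[Mapping[str, str], Sequence[str], None] = None,
) -> list[StructuredSection]:
    """Split an abstract into header-delimited sections.

    Headers are matched case-sensitively as ALL-CAPS vocabulary entries
    followed by ``:``.  Text before the first header becomes one
    ``UNSTRUCTURED`` section; if no header is found the whole text is one
    ``UNSTRUCTURED`` section.  Each section's ``text`` is the raw remainder
    after the header token (whitespace preserved), so the sections
    partition the input exactly.
    """
    if not abstract_text:
        return []
    vocab = _normalize_vocabulary(header_vocabulary)
    if not vocab:
        raise ValueError("header vocabulary must be non-empty")
    matches = list(_compile_header_re(vocab).finditer(abstract_text))
    sections: list[StructuredSection] = []
    if not matches:
        return [StructuredSection(UNSTRUCTURED, "", abstract_text,
                                  (0, len(abstract_text)))]
    if matches[0].start() > 0:
        sections.append(StructuredSection(
            UNSTRUCTURED, "", abstract_text[: matches[0].start()],
            (0, matches[0].start())))
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(abstract_text)
        raw_header = m.group(0)
        sections.append(StructuredSection(
            label=vocab[raw_header[:-1]],
            raw_header=raw_header,
            text=abstract_text[m.end(): end],
            span=(m.start(), end)))
    return sections


# ---------------------------------------------------------------------------
# Schwartz & Hearst abbreviation detection
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]*)\)")
_WORD_RE = re.compile(r"\S+")


def _is_candidate_short_form(sf: str) -> bool:
    if not 2 <= len(sf) <= 10:
        return False
    if len(sf.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    return sf[0].isalnum()


def _first_alnum(s: str) -> str:
    for ch in s:
        if ch.isalnum():
            return ch
    return ""


def _chars_in_order(sf: str, candidate: str) -> bool:
    """All alphanumeric characters of *sf* occur in *candidate* in order
    (case-insensitive), the first anchored at the very start."""
    chars = [c.lower() for c in sf if c.isalnum()]
    if not chars:
        return False
    cand = candidate.lower()
    if not cand or cand[0] != chars[0]:
        return False
    pos = 1
    for c in chars[1:]:
        idx = cand.find(c, pos)
        if idx < 0:
            return False
        pos = idx + 1
    return True


def find_abbreviations(text: str) -> list[AbbreviationDefinition]:
    """Detect locally defined abbreviations (Schwartz & Hearst matching).

    A candidate short form is a parenthesized token of 2-10 characters, at
    most two words, containing at least one letter, first character
    alphanumeric.  Its long form is the shortest word sequence immediately
    preceding the open parenthesis -- searched within
    ``min(|SF|+5, |SF|*2)`` words -- that contains every alphanumeric
    character of the short form in order (case-insensitive), with the
    short form's first character at the start of a word.  Candidates with
    no valid long form are dropped.  Definitions are returned in document
    order; their spans never overlap.
    """
    out: list[AbbreviationDefinition] = []
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not _is_candidate_short_form(sf):
            continue
        words = list(_WORD_RE.finditer(text, 0, m.start()))
        window = min(len(sf) + 5, len(sf) * 2)
        first = _first_alnum(sf).lower()
        long_form = None
        # shortest match first: start as late as possible
        for i in range(len(words) - 1, max(len(words) - window, 0) - 1, -1):
            head = _first_alnum(words[i].group(0)).lower()
            if head != first:
                continue
            candidate = text[words[i].start(): words[-1].end()]
            if _chars_in_order(sf, candidate):
                long_form = candidate
                break
        if long_form is None or long_form.lower() == sf.lower():
            continue
        out.append(AbbreviationDefinition(
            short_form=sf, long_form=long_form,
            definition_span=(m.start(), m.end())))
    return out


def expand_abbreviations(
    section_text: str, defs: Sequence[AbbreviationDefinition]
) -> str:
    """Replace standalone short-form occurrences by their long forms.

    Matching is case-sensitive and word-bounded, so ``SAD`` inside
    ``SADNESS`` (or a plural ``SADs``) is never touched.  Longer short
    forms are substituted first so one expansion cannot clobber another.
    Conflicting definitions of the same short form keep the first and log
    a warning; the text is otherwise unchanged.
    """
    chosen: dict[str, str] = {}
    for d in defs:
        if d.short_form in chosen:
            if chosen[d.short_form] != d.long_form:
                logger.warning(
                    "conflicting definitions for %r: keeping %r, ignoring %r",
                    d.short_form, chosen[d.short_form], d.long_form)
            continue
        chosen[d.short_form] = d.long_form
    result = section_text
    for sf in sorted(chosen, key=len, reverse=True):
        pattern = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(sf) + r"(?![A-Za-z0-9])")
        result = pattern.sub(lambda _m, lf=chosen[sf]: lf, result)
    return result


# ---------------------------------------------------------------------------
# Conclusion extraction
# ---------------------------------------------------------------------------

def default_mesh_uri(descriptor_ui: str) -> str:
    """Map a MeSH descriptor UI (e.g. ``D016574``) to its identifier IRI."""
    return MESH_NAMESPACE + descriptor_ui


def extract_conclusion_atags(
    record: AbstractRecord,
    mesh_uri_scheme: Callable[[str], str] = default_mesh_uri,
    *,
    base_uri: str,
    header_vocabulary: Union[Mapping[str, str], Sequence[str], None] = None,
) -> list[Atag]:
    """Turn a structured abstract's conclusion into one MeSH-tagged aTag.

    The abstract is segmented; if a CONCLUSIONS section exists, its body
    (abbreviations expanded using definitions gathered from the whole
    abstract) becomes the aTag text, the record's MeSH descriptors become
    the tags, and the canonical article URL becomes the provenance.
    Returns an empty list for unstructured abstracts or abstracts without
    a conclusion section.
    """
    sections = segment_abstract(record.abstract_text, header_vocabulary)
    conclusion = next((s for s in sections if s.label == "CONCLUSIONS"), None)
    if conclusion is None:
        return []
    defs = find_abbreviations(record.abstract_text)
    text = expand_abbreviations(conclusion.text, defs).strip()
    if not text:
        return []
    entities = [
        OntologyEntity(uri=mesh_uri_scheme(ui), preferred_label=label,
                       source_vocabulary=guess_vocabulary(mesh_uri_scheme(ui)))
        for ui, label in record.mesh_terms
    ]
    return [make_atag(
        text, entities,
        provenance_uri=PUBMED_URI_TEMPLATE.format(pmid=record.pmid),
        base_uri=base_uri)]


# ---------------------------------------------------------------------------
# Record I/O (line-delimited JSON)
# ---------------------------------------------------------------------------

def records_from_jsonl(source: Union[str, Path, Iterable[str]]) -> list[AbstractRecord]:
    """Read abstract records from line-delimited JSON.

    Each line is one object with fields ``pmid``, ``title``, ``abstract``
    and ``mesh`` (a list of ``{"ui": ..., "label": ...}``).
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source
    records = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"line {lineno}: invalid record: {exc}") from exc
        records.append(AbstractRecord(
            pmid=str(obj["pmid"]),
            title=obj.get("title", ""),
            abstract_text=obj.get("abstract", ""),
            mesh_terms=tuple((m["ui"], m["label"]) for m in obj.get("mesh", []))))
    return records


def records_to_jsonl(records: Iterable[AbstractRecord]) -> str:
    """Serialize abstract records as line-delimited JSON (inverse of
    :func:`records_from_jsonl`)."""
    lines = []
    for r in records:
        lines.append(json.dumps({
            "pmid": r.pmid,
            "title": r.title,
            "abstract": r.abstract_text,
            "mesh": [{"ui": ui, "label": label} for ui, label in r.mesh_terms],
        }, ensure_ascii=False))
    return "\n".join(lines) + ("\n" if lines else "")
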