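"""Deterministic generators for every input the toolkit consumes.

All tests and demonstrations run from generated data: abstract corpora
with planted section headers and abbreviation definitions, a small named
drug/company world for the explorer, and SIDER-style side-effect tables.
Each generator is a pure function of its parameters (seeded PRNG, no
clock, no network) and returns ground truth alongside the data, so the
generator itself serves as the oracle for the processing pipeline.

The generated text is template-assembled from word lists rather than
natural language; nothing in the toolkit does statistical NLP beyond
pattern matching, so this is sufficient to exercise every rule.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .abstracts import (
    AbbreviationDefinition,
    AbstractRecord,
    StructuredSection,
    UNSTRUCTURED,
)
from .explorer import OntologyGraph
from .model import AtagCollection, OntologyEntity, guess_vocabulary, make_atag
from .tabular import EntityColumn, MappingConfig

__all__ = [
    "FixtureSpec",
    "AbstractGroundTruth",
    "gen_abstract_corpus",
    "gen_collection",
    "gen_drug_store",
    "gen_table",
    "TableGroundTruth",
]

DBPEDIA = "http://dbpedia.org/resource/"
FIXTURE_BASE_URI = "http://example.org/atags"

_FILLER_WORDS = [
    "patients", "treatment", "baseline", "cohort", "symptoms", "outcomes",
    "therapy", "responses", "measures", "clinical", "randomized", "placebo",
    "controlled", "significant", "improvement", "severity", "adverse",
    "events", "remission", "relapse", "assessment", "intervention",
    "followup", "scores", "weekly", "daily", "moderate", "chronic",
]

# words eligible for planted long forms; lowercase, parenthesis-free
_LONGFORM_WORDS = [
    "seasonal", "affective", "disorder", "behavioral", "cognitive",
    "therapy", "major", "depressive", "episode", "generalized", "anxiety",
    "panic", "response", "inventory", "rating", "scale", "quality",
    "life", "index", "treatment", "outcome", "functional", "magnetic",
    "resonance", "imaging", "heart", "variability", "social", "phobia",
    "working", "memory", "task", "negative", "emotion", "regulation",
]

_MESH_POOL = [
    ("D016574", "Seasonal Affective Disorder"),
    ("D003863", "Depression"),
    ("D001007", "Anxiety"),
    ("D003866", "Depressive Disorder"),
    ("D015928", "Cognitive Therapy"),
    ("D011613", "Psychotherapy"),
    ("D000928", "Antidepressive Agents"),
    ("D008297", "Male"),
    ("D005260", "Female"),
    ("D011788", "Quality of Life"),
    ("D016896", "Treatment Outcome"),
    ("D001523", "Mental Disorders"),
]

# acronyms colliding with section headers would be segmented as headers
_FORBIDDEN_ACRONYMS = {
    "AIM", "AIMS",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated abstract corpus.

    ``structured_fraction`` of the ``n`` records (rounded half-up to an
    exact count) receive explicit INTRODUCTION/METHODS/RESULTS/CONCLUSIONS
    headers; the rest are free-running text.  Each structured abstract
    plants on average ``abbreviation_rate`` locally defined abbreviations
    in its introduction and uses them in its conclusion.
    """

    seed: int = 0
    n: int = 500
    structured_fraction: float = 0.5
    abbreviation_rate: float = 1.5


@dataclass(frozen=True)
class AbstractGroundTruth:
    """What the generator planted in one abstract record."""

    structured: bool
    sections: tuple[StructuredSection, ...]
    abbreviations: tuple[AbbreviationDefinition, ...]
    expected_conclusion: Optional[str]  # expanded, stripped; None if none


def _sentence(rng: random.Random, n_words: int) -> str:
    words = [rng.choice(_FILLER_WORDS) for _ in range(n_words)]
    return (" ".join(words)).capitalize() + "."


def _pick_long_form(rng: random.Random, used_initials: set[str]
                    ) -> Optional[tuple[list[str], str]]:
    """Choose 2-3 words with pairwise-distinct initials; the acronym is
    their uppercased initials.  Distinct initials guarantee the detection
    rule recovers exactly the planted words."""
    for _ in range(50):
        k = rng.choice([2, 3])
        words = rng.sample(_LONGFORM_WORDS, k)
        initials = [w[0] for w in words]
        acro = "".join(initials).upper()
        if len(set(initials)) != k:
            continue
        if acro in _FORBIDDEN_ACRONYMS or initials[0] in used_initials:
            continue
        return words, acro
    return None


def _n_abbreviations(rng: random.Random, rate: float) -> int:
    base = int(rate)
    return base + (1 if rng.random() < rate - base else 0)


def gen_abstract_corpus(spec: FixtureSpec
                        ) -> tuple[list[AbstractRecord], list[AbstractGroundTruth]]:
    """Generate an abstract corpus with exact per-record ground truth.

    Exactly ``round(spec.n * spec.structured_fraction)`` records are
    structured (half-up rounding); their positions are a deterministic
    sample.  Ground truth records every section span, every planted
    abbreviation definition, and the expected abbreviation-expanded
    conclusion body, computed independently of the processing pipeline.
    """
    if not 0.0 <= spec.structured_fraction <= 1.0:
        raise ValueError("structured_fraction must be in [0, 1]")
    rng = random.Random(spec.seed)
    n_structured = int(spec.n * spec.structured_fraction + 0.5)
    structured_at = set(rng.sample(range(spec.n), n_structured))
    records: list[AbstractRecord] = []
    truths: list[AbstractGroundTruth] = []
    for i in range(spec.n):
        pmid = str(10_000_000 + i)
        mesh = tuple(rng.sample(_MESH_POOL, rng.randint(1, 5)))
        title = _sentence(rng, rng.randint(4, 8))[:-1]
        if i in structured_at:
            record, truth = _gen_structured(rng, pmid, title, mesh, spec)
        else:
            record, truth = _gen_unstructured(rng, pmid, title, mesh)
        records.append(record)
        truths.append(truth)
    return records, truths


def _gen_unstructured(rng, pmid, title, mesh):
    body = " ".join(_sentence(rng, rng.randint(6, 12))
                    for _ in range(rng.randint(2, 4)))
    record = AbstractRecord(pmid=pmid, title=title, abstract_text=body,
                            mesh_terms=mesh)
    truth = AbstractGroundTruth(
        structured=False,
        sections=(StructuredSection(UNSTRUCTURED, "", body, (0, len(body))),),
        abbreviations=(), expected_conclusion=None)
    return record, truth


def _gen_structured(rng, pmid, title, mesh, spec: FixtureSpec):
    # plant abbreviation definitions for the introduction
    n_abbr = _n_abbreviations(rng, spec.abbreviation_rate)
    defs: list[tuple[str, str]] = []  # (long form phrase, acronym)
    used_initials: set[str] = set()
    used_acros: set[str] = set()
    for _ in range(n_abbr):
        picked = _pick_long_form(rng, used_initials)
        if picked is None:
            break
        words, acro = picked
        if acro in used_acros:
            continue
        defs.append((" ".join(words), acro))
        used_acros.add(acro)
        used_initials.add(words[0][0])

    intro_bits = []
    for long_form, acro in defs:
        intro_bits.append(
            f"Numerous {rng.choice(_FILLER_WORDS)} with {long_form} ({acro}) "
            f"were {rng.choice(_FILLER_WORDS)} at {rng.choice(_FILLER_WORDS)}.")
    intro_bits.append(_sentence(rng, rng.randint(5, 9)))
    intro_body = " ".join(intro_bits)

    methods_body = _sentence(rng, rng.randint(6, 10))
    results_body = _sentence(rng, rng.randint(6, 10))

    tail = (f"{rng.choice(_FILLER_WORDS)} with {rng.choice(_FILLER_WORDS)} "
            f"{rng.choice(_FILLER_WORDS)}.")
    if defs:
        subjects = " and ".join(acro for _lf, acro in defs)
        subjects_expanded = " and ".join(lf for lf, _a in defs)
        conclusion_body = f"This study shows that {subjects} is effectively treated {tail}"
        expected_conclusion = (
            f"This study shows that {subjects_expanded} is effectively treated {tail}")
    else:
        conclusion_body = "This study shows that " + tail
        expected_conclusion = conclusion_body

    # assemble with exact offsets; sections partition the text
    parts: list[str] = []
    sections: list[StructuredSection] = []
    abbreviations: list[AbbreviationDefinition] = []
    pos = 0
    bodies = [("INTRODUCTION", intro_body), ("METHODS", methods_body),
              ("RESULTS", results_body), ("CONCLUSIONS", conclusion_body)]
    for j, (label, body) in enumerate(bodies):
        header = label + ":"
        start = pos
        text = " " + body + (" " if j < len(bodies) - 1 else "")
        parts.append(header + text)
        pos += len(header) + len(text)
        sections.append(StructuredSection(label, header, text, (start, pos)))
    abstract = "".join(parts)

    for long_form, acro in defs:
        marker = f"({acro})"
        at = abstract.index(marker)
        abbreviations.append(AbbreviationDefinition(
            short_form=acro, long_form=long_form,
            definition_span=(at, at + len(marker))))

    record = AbstractRecord(pmid=pmid, title=title, abstract_text=abstract,
                            mesh_terms=mesh)
    truth = AbstractGroundTruth(
        structured=True, sections=tuple(sections),
        abbreviations=tuple(abbreviations),
        expected_conclusion=expected_conclusion)
    return record, truth


# ---------------------------------------------------------------------------
# Random aTag collections (inputs for serialization round-trip testing)
# ---------------------------------------------------------------------------

_ENTITY_POOL_SPECS = [
    ("http://dbpedia.org/resource/", ["Huperzine_A", "NMDA_receptor",
                                      "Celecoxib", "Serotonin", "Dopamine"]),
    ("http://purl.obolibrary.org/obo/", ["GO_0048019", "GO_0005515",
                                         "CHEBI_15355", "DOID_1596"]),
    ("http://id.nlm.nih.gov/mesh/", ["D016574", "D003863", "D000928"]),
    ("http://example.org/vocab#", ["alpha", "beta", "gamma"]),
]


def _entity_pool() -> list[OntologyEntity]:
    pool = []
    for prefix, names in _ENTITY_POOL_SPECS:
        for name in names:
            uri = prefix + name
            pool.append(OntologyEntity(
                uri=uri, preferred_label=name.replace("_", " "),
                source_vocabulary=guess_vocabulary(uri)))
    return pool


def gen_collection(seed: int = 0, n_atags: int = 5,
                   base_uri: str = FIXTURE_BASE_URI) -> AtagCollection:
    """Generate a random but deterministic aTag collection.

    Snippet texts are word salad (with occasional multi-space runs and
    non-ASCII characters, to exercise escaping and whitespace handling);
    tag sets of size 0-5 are drawn from a fixed labeled entity pool, so
    every entity keeps one consistent label across the collection.
    Timestamps, when present, are fixed offsets from a constant epoch --
    never the wall clock.
    """
    from datetime import datetime, timedelta, timezone

    rng = random.Random(seed)
    pool = _entity_pool()
    epoch = datetime(2010, 6, 22, tzinfo=timezone.utc)
    collection = AtagCollection(base_uri=base_uri)
    for i in range(n_atags):
        words = [rng.choice(_FILLER_WORDS) for _ in range(rng.randint(3, 10))]
        if rng.random() < 0.3:
            words.insert(rng.randrange(len(words)), "naïve <cohort> & controls")
        sep = "  " if rng.random() < 0.2 else " "
        text = f"statement {i}: " + sep.join(words)
        tags = rng.sample(pool, rng.randint(0, 5))
        provenance = (f"https://pubmed.ncbi.nlm.nih.gov/{rng.randint(1, 10**7)}/"
                      if rng.random() < 0.5 else None)
        created = (epoch + timedelta(minutes=rng.randint(0, 10**6))
                   if rng.random() < 0.5 else None)
        collection.atags.append(make_atag(
            text, tags, provenance_uri=provenance, base_uri=base_uri,
            created=created))
    return collection


# ---------------------------------------------------------------------------
# Explorer fixture: a small named drug / company world
# ---------------------------------------------------------------------------

def _ent(name: str, label: Optional[str] = None) -> OntologyEntity:
    uri = DBPEDIA + name
    return OntologyEntity(uri=uri,
                          preferred_label=label or name.replace("_", " "),
                          source_vocabulary=guess_vocabulary(uri))


def gen_drug_store(seed: int = 0) -> tuple[AtagCollection, OntologyGraph]:
    """A small named world for exploratory search.

    Three pharmaceutical companies, six drugs with a class hierarchy
    (Celecoxib is a pyrazole, Atorvastatin a statin, ... all under a
    'drug' root), side effects, plus person/institution distractor
    statements that also mention company names -- so a keyword search for
    a company yields mixed result types and narrowing by the 'drug'
    broader tag is meaningful.  The seed only shuffles statement order;
    the world itself is fixed.
    """
    rng = random.Random(seed)

    drug = _ent("Drug", "drug")
    pyrazole = _ent("Pyrazole", "pyrazole")
    statin = _ent("Statin", "statin")
    antibiotic = _ent("Antibiotic", "antibiotic")
    nicotinic = _ent("Nicotinic_agonist", "nicotinic agonist")
    symptom = _ent("Symptom", "symptom")
    agent = _ent("Agent", "agent")
    organization = _ent("Organization", "organization")
    person = _ent("Person", "person")

    celecoxib = _ent("Celecoxib")
    atorvastatin = _ent("Atorvastatin")
    azithromycin = _ent("Azithromycin")
    amoxicillin = _ent("Amoxicillin")
    varenicline = _ent("Varenicline")
    rosuvastatin = _ent("Rosuvastatin")

    pfizer = _ent("Pfizer")
    astrazeneca = _ent("AstraZeneca")
    gsk = _ent("GlaxoSmithKline")
    researcher = _ent("Maria_Keller", "Maria Keller")
    institute = _ent("Research_institute", "research institute")

    headache = _ent("Headache", "headache")
    nausea = _ent("Nausea", "nausea")

    g = OntologyGraph()
    for child, parent in [
        (pyrazole, drug), (statin, drug), (antibiotic, drug), (nicotinic, drug),
        (celecoxib, pyrazole), (atorvastatin, statin),
        (azithromycin, antibiotic), (amoxicillin, antibiotic),
        (varenicline, nicotinic), (rosuvastatin, statin),
        (headache, symptom), (nausea, symptom),
        (organization, agent), (person, agent),
        (pfizer, organization), (astrazeneca, organization), (gsk, organization),
        (researcher, person), (institute, organization),
    ]:
        g.add_entity(child)
        g.add_entity(parent)
        g.add_broader_edge(child.uri, parent.uri)

    statements = [
        ("Celecoxib is developed and manufactured by Pfizer",
         [celecoxib, pfizer]),
        ("Atorvastatin is marketed worldwide by Pfizer",
         [atorvastatin, pfizer]),
        ("Azithromycin was brought to market by Pfizer",
         [azithromycin, pfizer]),
        ("Varenicline is a Pfizer product prescribed for smoking cessation",
         [varenicline, pfizer]),
        ("Celecoxib has reported side effect headache",
         [celecoxib, headache]),
        ("Varenicline has reported side effect nausea",
         [varenicline, nausea]),
        ("Maria Keller is a senior researcher employed by Pfizer",
         [researcher, pfizer]),
        ("Pfizer funds a research institute in Galway",
         [pfizer, institute]),
        ("Rosuvastatin is manufactured by AstraZeneca",
         [rosuvastatin, astrazeneca]),
        ("Rosuvastatin has reported side effect nausea",
         [rosuvastatin, nausea]),
        ("Amoxicillin is manufactured by GlaxoSmithKline",
         [amoxicillin, gsk]),
        ("Amoxicillin has reported side effect headache",
         [amoxicillin, headache]),
    ]
    rng.shuffle(statements)
    collection = AtagCollection(base_uri=FIXTURE_BASE_URI)
    for text, entities in statements:
        collection.atags.append(
            make_atag(text, entities, base_uri=FIXTURE_BASE_URI))
    return collection, g


# ---------------------------------------------------------------------------
# Tabular fixture: SIDER-style drug / side-effect table
# ---------------------------------------------------------------------------

_TABLE_DRUGS = [
    ("Celecoxib", DBPEDIA + "Celecoxib"),
    ("Atorvastatin", DBPEDIA + "Atorvastatin"),
    ("Varenicline", DBPEDIA + "Varenicline"),
    ("Azithromycin", DBPEDIA + "Azithromycin"),
    ("Rosuvastatin", DBPEDIA + "Rosuvastatin"),
    ("Amoxicillin", DBPEDIA + "Amoxicillin"),
]

_TABLE_EFFECTS = [
    ("headache", DBPEDIA + "Headache"),
    ("nausea", DBPEDIA + "Nausea"),
    ("dizziness", DBPEDIA + "Dizziness"),
    ("fatigue", DBPEDIA + "Fatigue"),
    ("insomnia", DBPEDIA + "Insomnia"),
    ("rash", DBPEDIA + "Rash"),
]


@dataclass(frozen=True)
class TableGroundTruth:
    """Expected per-row conversion verdicts for a generated table."""

    ok: bool
    text: Optional[str] = None
    tag_uris: tuple[str, ...] = ()
    reason: Optional[str] = None


def gen_table(seed: int = 0, n_rows: int = 20, bad_row_rate: float = 0.0
              ) -> tuple[str, MappingConfig, list[TableGroundTruth]]:
    """Generate a SIDER-style drug/side-effect TSV plus mapping config.

    Rows pair a drug with a side effect (pairs are unique, so minted aTag
    identifiers never collide).  A ``bad_row_rate`` fraction of rows
    (rounded half-up) is truncated after the first column, which makes
    the columns referenced by the mapping unresolvable -- the expected
    verdict for those rows is a skip (permissive) or abort (strict).
    Some good rows have an empty URI cell for the side effect and yield a
    one-tag aTag.  Ground truth lists each row's expected text and tags.
    """
    if n_rows > len(_TABLE_DRUGS) * len(_TABLE_EFFECTS):
        raise ValueError("n_rows exceeds the number of distinct drug/effect pairs")
    rng = random.Random(seed)
    pairs = [(d, e) for d in _TABLE_DRUGS for e in _TABLE_EFFECTS]
    rng.shuffle(pairs)
    pairs = pairs[:n_rows]
    n_bad = int(n_rows * bad_row_rate + 0.5)
    bad_at = set(rng.sample(range(n_rows), n_bad))
    cfg = MappingConfig(
        text_template="{drug} has reported side effect {effect}",
        entity_columns=(
            EntityColumn(column="drug", uri_column="drug_uri"),
            EntityColumn(column="effect", uri_column="effect_uri"),
        ),
        delimiter="\t")
    lines = ["drug\tdrug_uri\teffect\teffect_uri"]
    truth: list[TableGroundTruth] = []
    for i, ((drug, drug_uri), (effect, effect_uri)) in enumerate(pairs):
        if i in bad_at:
            lines.append(drug)  # truncated row: referenced columns missing
            truth.append(TableGroundTruth(ok=False, reason="missing column"))
            continue
        if rng.random() < 0.15:
            effect_uri = ""  # empty cell: no tag for this column
        lines.append(f"{drug}\t{drug_uri}\t{effect}\t{effect_uri}")
        tags = (drug_uri,) + ((effect_uri,) if effect_uri else ())
        truth.append(TableGroundTruth(
            ok=True, text=f"{drug} has reported side effect {effect}",
            tag_uris=tags))
    return "\n".join(lines) + "\n", cfg, truth
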