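import pytest
from hypothesis import settings

from atagkit import AtagCollection, OntologyEntity, make_atag
from atagkit.abstracts import AbstractRecord

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

BASE = "http://example.org/atags"

HUPERZINE_TEXT = (
    "Huperzine A acts as a non-competitive antagonist of the NMDA receptor")

HUPERZINE_ENTITIES = [
    OntologyEntity("http://dbpedia.org/resource/Huperzine_A",
                   "Huperzine A", "dbpedia"),
    OntologyEntity("http://purl.obolibrary.org/obo/GO_0048019",
                   "receptor antagonist activity", "obo"),
    OntologyEntity("http://dbpedia.org/resource/NMDA_receptor",
                   "NMDA receptor", "dbpedia"),
]

SAD_ABSTRACT = (
    "INTRODUCTION: Seasonal affective disorder (SAD) is common in northern "
    "countries. CONCLUSIONS: This study shows that SAD is effectively "
    "treated with bright light therapy.")


@pytest.fixture
def huperzine_atag():
    """The exemplary bookmarklet-created aTag: one highlighted sentence
    tagged with a drug, a molecular function and a receptor."""
    return make_atag(
        HUPERZINE_TEXT, HUPERZINE_ENTITIES,
        provenance_uri="https://pubmed.ncbi.nlm.nih.gov/18771181/",
        base_uri=BASE)


@pytest.fixture
def huperzine_collection(huperzine_atag):
    return AtagCollection(base_uri=BASE, atags=[huperzine_atag])


@pytest.fixture
def sad_record():
    """A structured abstract defining SAD locally and using the short form
    in its conclusion."""
    return AbstractRecord(
        pmid="11111111", title="Light therapy for seasonal depression",
        abstract_text=SAD_ABSTRACT,
        mesh_terms=(("D016574", "Seasonal Affective Disorder"),))
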