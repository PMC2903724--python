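"""Structured-abstract processing: segmentation, abbreviation handling,
conclusion extraction."""

import pytest
from hypothesis import given, strategies as st

from atagkit.abstracts import (
    AbbreviationDefinition,
    UNSTRUCTURED,
    expand_abbreviations,
    extract_conclusion_atags,
    find_abbreviations,
    records_from_jsonl,
    records_to_jsonl,
    segment_abstract,
)
from atagkit.fixtures import FixtureSpec, gen_abstract_corpus

from conftest import BASE, SAD_ABSTRACT


class TestSegmentation:
    def test_sad_abstract_splits_into_intro_and_conclusions(self):
        sections = segment_abstract(SAD_ABSTRACT)
        assert [s.label for s in sections] == ["INTRODUCTION", "CONCLUSIONS"]
        assert sections[0].text.strip().startswith(
            "Seasonal affective disorder (SAD) is common")
        assert sections[1].text.strip().startswith(
            "This study shows that SAD is effectively treated")

    def test_empty_abstract_yields_no_sections(self):
        assert segment_abstract("") == []

    def test_headerless_text_is_one_unstructured_section(self):
        text = "A plain abstract without any headers."
        (s,) = segment_abstract(text)
        assert s.label == UNSTRUCTURED and s.text == text
        assert s.span == (0, len(text))

    def test_preamble_before_first_header_is_unstructured(self):
        text = "Preamble words. METHODS: something. CONCLUSION: the end."
        sections = segment_abstract(text)
        assert [s.label for s in sections] == [
            UNSTRUCTURED, "METHODS", "CONCLUSIONS"]
        assert sections[0].text == "Preamble words. "

    def test_synonyms_map_to_canonical_labels(self):
        text = ("AIMS: a. MATERIALS AND METHODS: b. FINDINGS: c. "
                "INTERPRETATION: d.")
        assert [s.label for s in segment_abstract(text)] == [
            "OBJECTIVES", "METHODS", "RESULTS", "CONCLUSIONS"]

    def test_lowercase_headers_not_matched(self):
        (s,) = segment_abstract("conclusions: not a real header.")
        assert s.label == UNSTRUCTURED

    def test_custom_vocabulary_overrides_default(self):
        sections = segment_abstract(
            "SCOPE: x. VERDICT: y.", {"SCOPE": "BACKGROUND",
                                      "VERDICT": "CONCLUSIONS"})
        assert [s.label for s in sections] == ["BACKGROUND", "CONCLUSIONS"]

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property_on_generated_abstracts(self, seed):
        """Concatenating raw_header + text of all sections reconstructs
        the abstract byte for byte."""
        records, _ = gen_abstract_corpus(FixtureSpec(seed=seed, n=20))
        for r in records:
            sections = segment_abstract(r.abstract_text)
            rebuilt = "".join(s.raw_header + s.text for s in sections)
            assert rebuilt == r.abstract_text
            offsets = [s.span for s in sections]
            assert offsets == sorted(offsets)
            assert all(a[1] == b[0] for a, b in zip(offsets, offsets[1:]))


class TestFindAbbreviations:
    def test_sad_definition_detected(self):
        defs = find_abbreviations(SAD_ABSTRACT)
        assert [(d.short_form, d.long_form) for d in defs] == [
            ("SAD", "Seasonal affective disorder")]
        d = defs[0]
        assert SAD_ABSTRACT[slice(*d.definition_span)] == "(SAD)"

    @pytest.mark.parametrize("text", [
        "the mean (n = 12) was",          # 3 words, no valid shape
        "values rose (12.5) overall",     # no letter
        "a very long phrase (not an acronym whatsoever) here",
        "trailing thought (c) here",      # too short
    ])
    def test_non_candidates_rejected(self, text):
        assert find_abbreviations(text) == []

    def test_long_form_is_shortest_valid_word_sequence(self):
        defs = find_abbreviations(
            "patients with chronic heart failure (CHF) were enrolled")
        assert [(d.short_form, d.long_form) for d in defs] == [
            ("CHF", "chronic heart failure")]

    def test_candidate_without_matching_long_form_dropped(self):
        assert find_abbreviations("the result (XQZ) was strange") == []

    def test_spans_never_overlap_and_in_document_order(self):
        text = ("Seasonal affective disorder (SAD) and cognitive behavioral "
                "therapy (CBT) were compared.")
        defs = find_abbreviations(text)
        assert [d.short_form for d in defs] == ["SAD", "CBT"]
        spans = [d.definition_span for d in defs]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_pairs_recovered_with_full_precision_and_recall(self, seed):
        records, truths = gen_abstract_corpus(
            FixtureSpec(seed=seed, n=50, abbreviation_rate=1.5))
        for r, t in zip(records, truths):
            assert find_abbreviations(r.abstract_text) == list(t.abbreviations)


class TestExpandAbbreviations:
    SAD_DEF = AbbreviationDefinition(
        "SAD", "Seasonal affective disorder", (0, 5))

    def test_worked_example_expands_exactly(self):
        out = expand_abbreviations(
            "CONCLUSIONS: This study shows that SAD is effectively treated "
            "with bright light.", [self.SAD_DEF])
        assert out == ("CONCLUSIONS: This study shows that Seasonal affective "
                       "disorder is effectively treated with bright light.")

    def test_no_definitions_is_identity(self):
        text = "Anything at all, with SAD even."
        assert expand_abbreviations(text, []) == text

    def test_word_boundaries_respected(self):
        out = expand_abbreviations("SADNESS and SADs and SAD.", [self.SAD_DEF])
        assert out == "SADNESS and SADs and Seasonal affective disorder."

    def test_case_sensitive(self):
        assert expand_abbreviations("sad but true", [self.SAD_DEF]) == "sad but true"

    def test_conflicting_definitions_keep_first_and_warn(self, caplog):
        other = AbbreviationDefinition("SAD", "something altogether different",
                                       (10, 15))
        with caplog.at_level("WARNING"):
            out = expand_abbreviations("SAD", [self.SAD_DEF, other])
        assert out == "Seasonal affective disorder"
        assert any("conflicting" in r.message for r in caplog.records)

    def test_longer_short_forms_substituted_first(self):
        defs = [AbbreviationDefinition("SA", "sinoatrial", (0, 1)),
                AbbreviationDefinition("SAD", "Seasonal affective disorder",
                                       (2, 3))]
        assert expand_abbreviations("SAD and SA", defs) == (
            "Seasonal affective disorder and sinoatrial")

    @given(st.text(alphabet="abS AD.", max_size=60))
    def test_expansion_idempotent_when_long_forms_lack_short_forms(self, text):
        out1 = expand_abbreviations(text, [self.SAD_DEF])
        assert expand_abbreviations(out1, [self.SAD_DEF]) == out1


class TestConclusionExtraction:
    def test_sad_record_yields_one_expanded_mesh_tagged_atag(self, sad_record):
        (a,) = extract_conclusion_atags(sad_record, base_uri=BASE)
        assert "Seasonal affective disorder is effectively treated" in a.text
        assert "SAD " not in a.text
        assert len(a.tags) == 1
        assert a.tags[0].uri == "http://id.nlm.nih.gov/mesh/D016574"
        assert a.tags[0].preferred_label == "Seasonal Affective Disorder"
        assert a.provenance_uri == "https://pubmed.ncbi.nlm.nih.gov/11111111/"

    def test_headerless_record_yields_nothing(self, sad_record):
        from dataclasses import replace
        rec = replace(sad_record, abstract_text="No headers in this one.")
        assert extract_conclusion_atags(rec, base_uri=BASE) == []

    def test_empty_abstract_yields_nothing(self, sad_record):
        from dataclasses import replace
        rec = replace(sad_record, abstract_text="")
        assert extract_conclusion_atags(rec, base_uri=BASE) == []

    def test_corpus_emission_count_matches_structured_fraction(self):
        records, truths = gen_abstract_corpus(
            FixtureSpec(seed=11, n=100, structured_fraction=0.3))
        emitted = [extract_conclusion_atags(r, base_uri=BASE) for r in records]
        assert sum(len(e) for e in emitted) == 30
        for e, t in zip(emitted, truths):
            if t.structured:
                assert e[0].text == t.expected_conclusion

    def test_end_to_end_determinism(self, sad_record):
        from atagkit import AtagCollection, atags_to_turtle
        runs = []
        for _ in range(2):
            atags = extract_conclusion_atags(sad_record, base_uri=BASE)
            runs.append(atags_to_turtle(
                AtagCollection(base_uri=BASE, atags=atags)))
        assert runs[0] == runs[1]


def test_record_jsonl_roundtrip(sad_record):
    text = records_to_jsonl([sad_record])
    assert records_from_jsonl(text.splitlines()) == [sad_record]
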