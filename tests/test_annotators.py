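"""Tagger grammars, dictionary lookup, crash isolation, external hosting."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from sia.annotators import (
    Annotation,
    DictionaryError,
    DictionaryAnnotator,
    MirnaAnnotator,
    MutationAnnotator,
    TermDictionary,
    build_default_annotators,
    build_default_registry,
    check_offsets,
    load_dictionary,
    normalize_term,
    safe_annotate,
)
from sia.bridge import ExternalAnnotatorBridge


class TestMirnaGrammar:
    def test_species_prefixed_mention_with_arm(self):
        (a,) = MirnaAnnotator().annotate("hsa-miR-21-5p is upregulated", "A", "d1")
        assert (a.text, a.start, a.end) == ("hsa-miR-21-5p", 0, 13)
        assert a.type == "MIRNA" and a.score == 1.0

    def test_multiple_mentions(self):
        anns = MirnaAnnotator().annotate("let-7b and miR-146a", "A", "d1")
        assert [a.text for a in anns] == ["let-7b", "miR-146a"]

    @pytest.mark.parametrize(
        "negative", ["smirnoff", "mirage", "mir21", "amiR-21", "let seven"]
    )
    def test_word_boundary_negatives(self, negative):
        assert MirnaAnnotator().annotate(negative, "A", "d1") == []

    @pytest.mark.parametrize(
        "mention", ["mir-9", "lin-4", "MiR-155", "mmu-let-7a-1-3p", "miR-7641-2"]
    )
    def test_grammar_positives(self, mention):
        anns = MirnaAnnotator().annotate(f"see {mention} here", "A", "d1")
        assert [a.text for a in anns] == [mention]

    def test_longest_match_wins(self):
        (a,) = MirnaAnnotator().annotate("miR-21-5p", "A", "d1")
        assert a.text == "miR-21-5p"  # not just miR-21


class TestMutationGrammar:
    def test_one_letter_substitution_offsets(self):
        (a,) = MutationAnnotator().annotate("the BRAF V600E mutation", "A", "d1")
        assert (a.text, a.start, a.end) == ("V600E", 9, 14)

    def test_three_letter_and_cdna_forms(self):
        anns = MutationAnnotator().annotate("p.Val600Glu and c.1799T>A", "A", "d1")
        assert [a.text for a in anns] == ["p.Val600Glu", "c.1799T>A"]

    @pytest.mark.parametrize(
        "negative",
        ["E2F4", "H2O2", "BRCA1", "CDKN2A", "V600", "600E", "c.123A>Z", "X100Y"],
    )
    def test_gene_like_and_malformed_tokens_rejected(self, negative):
        # X is not a valid amino-acid letter; trailing digits break the
        # letter-digits-letter shape; Z is not a nucleotide
        assert MutationAnnotator().annotate(negative, "A", "d1") == []

    @pytest.mark.parametrize(
        "mention", ["Val600Glu", "A54T", "c.35G>A", "p.Gly12Asp", "W515L"]
    )
    def test_grammar_positives(self, mention):
        anns = MutationAnnotator().annotate(f"carrying {mention} allele", "A", "d1")
        assert [a.text for a in anns] == [mention]


class TestDictionary:
    def test_load_counts_entries(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("breast cancer\tC1\nlung cancer\tC2\nasthma\tC3\n")
        d = load_dictionary(str(path))
        assert len(d) == 3

    def test_normalization_collision_keeps_first(self, tmp_path, caplog):
        path = tmp_path / "dict.tsv"
        path.write_text("Breast Cancer\tC1\nbreast cancer\tC2\n")
        with caplog.at_level(logging.WARNING):
            d = load_dictionary(str(path))
        assert len(d) == 1
        assert d.entries["breast cancer"] == "C1"
        assert any("duplicate" in r.message for r in caplog.records)

    def test_max_term_tokens(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("type 2 diabetes mellitus\tC1\n")
        assert load_dictionary(str(path)).max_term_tokens == 4

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("good term\tC1\nno_tab_here\n")
        with pytest.raises(DictionaryError, match=":2"):
            load_dictionary(str(path))

    def test_empty_file_is_valid_empty_dictionary(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("")
        assert len(load_dictionary(str(path))) == 0

    def test_normalize_strips_edge_punctuation(self):
        assert normalize_term("  Breast   Cancer, ") == "breast cancer"


class TestDictionaryMatching:
    @pytest.fixture
    def tagger(self):
        d = TermDictionary.from_terms([("breast cancer", "C1"), ("cancer", "C2")])
        return DictionaryAnnotator("DISEASE", d)

    def test_leftmost_longest_wins(self, tagger):
        (a,) = tagger.annotate("breast cancer study", "A", "d1")
        assert (a.text, a.start, a.end) == ("breast cancer", 0, 13)

    def test_token_boundary_requirement(self, tagger):
        assert tagger.annotate("anticancer", "A", "d1") == []

    def test_original_casing_preserved(self):
        d = TermDictionary.from_terms([("cancer", "C2")])
        (a,) = DictionaryAnnotator("DISEASE", d).annotate("Cancer of the lung", "A", "d1")
        assert a.text == "Cancer"

    def test_scan_resumes_past_match_no_overlap(self, tagger):
        anns = tagger.annotate("breast cancer cancer clinic", "A", "d1")
        assert [a.text for a in anns] == ["breast cancer", "cancer"]
        assert anns[0].end < anns[1].start


class TestInterfaceContract:
    @pytest.fixture(params=["mutation", "mirna", "disease"])
    def annotator(self, request):
        return build_default_annotators()[request.param]

    def test_empty_text_empty_result(self, annotator):
        assert annotator.annotate("", "A", "d1") == []

    def test_offset_invariant_on_mixed_text(self, annotator):
        text = "melanoma with BRAF V600E and hsa-miR-21-5p; see let-7b, c.35G>A"
        anns = annotator.annotate(text, "A", "d1")
        check_offsets(text, anns)

    def test_composition_equals_union(self):
        text = "melanoma near V600E and miR-21"
        annos = build_default_annotators()
        separate = []
        for name in ("mutation", "mirna", "disease"):
            separate.extend(annos[name].annotate(text, "A", "d1"))
        joint = []
        for name in ("disease", "mirna", "mutation"):  # order-independent
            joint.extend(annos[name].annotate(text, "A", "d1"))
        assert sorted(separate) == sorted(joint)
        assert len(separate) == 3

    def test_determinism(self, annotator):
        text = "V600E miR-21 melanoma " * 3
        first = annotator.annotate(text, "A", "d1")
        assert all(annotator.annotate(text, "A", "d1") == first for _ in range(3))


@pytest.mark.parametrize("name", ["mutation", "mirna", "disease"])
@given(text=st.text(
    alphabet=st.sampled_from(list("abcdef AC GT 123-.>pVGlu miRlet")),
    max_size=80,
))
@settings(derandomize=True, max_examples=80)
def test_offset_fidelity_on_random_text(name, text):
    annotator = build_default_annotators()[name]
    check_offsets(text, annotator.annotate(text, "A", "d1"))


class TestSafeAnnotate:
    class Crashing:
        name = "crashing"
        entity_type = "GENE"

        def annotate(self, text, section, document_id):
            raise RuntimeError("third-party tagger bug")

    def test_crash_becomes_empty_list_with_log(self, caplog):
        with caplog.at_level(logging.ERROR):
            result = safe_annotate(self.Crashing(), "any text", "A", "d1")
        assert result == []
        assert len([r for r in caplog.records if r.levelno == logging.ERROR]) == 1

    def test_healthy_annotator_passed_through(self):
        out = safe_annotate(MutationAnnotator(), "V600E", "A", "d1")
        assert [a.text for a in out] == ["V600E"]


class TestRegistryResolution:
    def test_direct_mapping(self):
        registry = build_default_registry()
        assert registry.resolve_queues({"MUTATION"}) == (
            {"q.annotator.mutation"}, set()
        )

    def test_deactivated_type_unserved(self):
        registry = build_default_registry()
        registry.deactivate("CHEMICAL")
        assert registry.resolve_queues({"CHEMICAL"}) == (set(), {"CHEMICAL"})

    def test_union_over_types(self):
        registry = build_default_registry()
        queues, unserved = registry.resolve_queues({"DISEASE", "MIRNA"})
        assert queues == {"q.annotator.disease", "q.annotator.mirna"}
        assert unserved == set()


class TestExternalBridge:
    def test_bridge_output_identical_to_embedded(self):
        text = "hsa-miR-21-5p near let-7b and V600E in melanoma"
        for name in ("mirna", "mutation"):
            embedded = build_default_annotators()[name].annotate(text, "A", "d1")
            with ExternalAnnotatorBridge(name) as bridge:
                external = bridge.annotate(text, "A", "d1")
            assert [a.to_dict() for a in external] == [a.to_dict() for a in embedded]


class TestAnnotationInvariants:
    def test_span_and_score_validated(self):
        with pytest.raises(ValueError):
            Annotation("d", "A", 5, 5, "GENE", 1.0, "")
        with pytest.raises(ValueError):
            Annotation("d", "A", 0, 1, "GENE", 1.5, "x")
        with pytest.raises(ValueError):
            Annotation("d", "X", 0, 1, "GENE", 1.0, "x")
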