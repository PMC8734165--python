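import pytest

from krc.corpus_io import ConceptHierarchy, split_sentences
from krc.instance_builder import (MASK_TOKEN, assign_answer, build_instances,
                                  build_query, extract_candidates,
                                  filter_hypernyms, mask_context,
                                  unmasked_tail_spans)
from krc.synthetic_data import SynthConfig, gen_corpus
from conftest import make_doc


def by_pair(cands):
    return {(c.head_id, c.tail_id): c for c in cands}


class TestExtractCandidates:
    def test_toy_doc_one_intra_two_inter(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        assert len(cands) == 3
        assert cands[("C1", "D1")].level == "intra"
        assert cands[("C1", "D2")].level == "inter"
        assert cands[("C1", "D2")].distance == 1
        assert cands[("C1", "D3")].level == "inter"
        assert cands[("C1", "D3")].distance == 3

    def test_distance_four_pair_dropped(self, toy_doc_distance4):
        cands = by_pair(extract_candidates(toy_doc_distance4))
        assert ("C1", "D3") not in cands
        assert len(cands) == 2

    def test_intra_wins_over_inter(self):
        # headache co-occurs in the title and again two sentences away
        doc = make_doc(
            "d3", "Aspirin and headache.",
            "Aspirin was given. Patients rested. Then headache returned.",
            [("Aspirin", "chemical", "C1"), ("headache", "disease", "D1")])
        split_sentences(doc)
        cands = by_pair(extract_candidates(doc))
        assert cands[("C1", "D1")].level == "intra"

    def test_no_pair_gets_both_levels(self, toy_doc):
        cands = extract_candidates(toy_doc)
        assert len({(c.head_id, c.tail_id) for c in cands}) == len(cands)

    def test_unresolved_mentions_excluded(self):
        doc = make_doc(
            "d4", "Aspirin and headache.", "Nothing else here.",
            [("Aspirin", "chemical", "-1"), ("headache", "disease", "D1")])
        split_sentences(doc)
        assert extract_candidates(doc) == []

    def test_requires_sentences(self, toy_doc):
        doc = make_doc("d5", "Aspirin here.", "No mentions.",
                       [("Aspirin", "chemical", "C1")])
        with pytest.raises(ValueError, match="sentences"):
            extract_candidates(doc)

    def test_full_document_context_ignores_distance(self, toy_doc_distance4):
        cands = by_pair(extract_candidates(toy_doc_distance4,
                                           full_document_context=True))
        assert ("C1", "D3") in cands
        first, last = cands[("C1", "D3")].sentence_window
        assert (first, last) == (0, len(toy_doc_distance4.sentences) - 1)


class TestMaskContext:
    def test_other_tail_entities_masked(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D3")])
        # window spans sentences 1-4; nausea (D2) and headache (D1) masked
        assert MASK_TOKEN in c.context
        assert "Nausea" not in c.context
        assert "Dizziness" in c.context

    def test_only_tail_mention_untouched(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D2")])
        assert "Nausea" in c.context

    def test_offset_map_recovers_document_span(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D3")])
        (span,) = unmasked_tail_spans(toy_doc, c)
        doc_span = c.to_document_span(*span)
        assert toy_doc.text[doc_span[0]:doc_span[1]] == "Dizziness"

    def test_span_inside_masked_region_unmappable(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D3")])
        idx = c.context.index(MASK_TOKEN)
        assert c.to_document_span(idx, idx + len(MASK_TOKEN)) is None

    def test_masking_disabled(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D3")], mask_other_tails=False)
        assert "Nausea" in c.context and MASK_TOKEN not in c.context


class TestFilterHypernyms:
    def test_ancestor_with_specific_entity_removed(self):
        doc = make_doc(
            "d6", "Aspirin and pain.", "Aspirin causes headache.",
            [("Aspirin", "chemical", "C1"), ("pain", "disease", "Dpain"),
             ("headache", "disease", "Dhead")])
        split_sentences(doc)
        cands = extract_candidates(doc)
        h = ConceptHierarchy(frozenset([("Dpain", "Dhead")]))
        kept = by_pair(filter_hypernyms(cands, h, doc))
        assert ("C1", "Dpain") not in kept
        assert ("C1", "Dhead") in kept

    def test_empty_hierarchy_removes_nothing(self, toy_doc):
        cands = extract_candidates(toy_doc)
        h = ConceptHierarchy(frozenset())
        assert filter_hypernyms(cands, h, toy_doc) == cands

    def test_ancestor_without_specific_entity_kept(self):
        doc = make_doc(
            "d7", "Aspirin and pain.", "Only pain here.",
            [("Aspirin", "chemical", "C1"), ("pain", "disease", "Dpain")])
        split_sentences(doc)
        cands = extract_candidates(doc)
        h = ConceptHierarchy(frozenset([("Dpain", "Dhead")]))
        assert by_pair(filter_hypernyms(cands, h, doc))

    def test_monotone_in_hierarchy(self, toy_doc):
        cands = extract_candidates(toy_doc)
        small = ConceptHierarchy(frozenset([("D1", "D2")]))
        large = ConceptHierarchy(frozenset([("D1", "D2"), ("D2", "D3")]))
        kept_small = {(c.head_id, c.tail_id)
                      for c in filter_hypernyms(cands, small, toy_doc)}
        kept_large = {(c.head_id, c.tail_id)
                      for c in filter_hypernyms(cands, large, toy_doc)}
        assert kept_large <= kept_small


class TestBuildQuery:
    @pytest.mark.parametrize("head,rel,ttype,style,expected", [
        ("flunitrazepan", "induce", "disease", "natural",
         "what disease does flunitrazepan induce"),
        ("flunitrazepan", "induce", "disease", "pseudo",
         "flunitrazepan induce disease"),
        ("aspirin", "react with", "chemical", "natural",
         "what chemical does aspirin react with"),
    ])
    def test_templates(self, head, rel, ttype, style, expected):
        assert build_query(head, rel, ttype, style) == expected

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError, match="style"):
            build_query("aspirin", "induce", "disease", "telepathic")

    def test_empty_head_rejected(self):
        with pytest.raises(ValueError):
            build_query("", "induce", "disease")


class TestAssignAnswer:
    def test_positive_answer_is_first_tail_mention(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D1")])
        assign_answer(c, toy_doc)
        assert c.context[c.answer_start:c.answer_end] == "headache"

    def test_negative_pair_gets_null(self, toy_doc):
        cands = by_pair(extract_candidates(toy_doc))
        c = mask_context(toy_doc, cands[("C1", "D3")])
        assign_answer(c, toy_doc)
        assert c.is_null

    def test_earliest_of_two_tail_mentions(self):
        doc = make_doc(
            "d8", "Aspirin study.",
            "Aspirin causes headache. Later headache worsened.",
            [("Aspirin", "chemical", "C1"), ("headache", "disease", "D1")],
            gold=[("C1", "D1", "CID")])
        split_sentences(doc)
        cands = by_pair(extract_candidates(doc))
        c = mask_context(doc, cands[("C1", "D1")])
        assign_answer(c, doc)
        first = c.context.index("headache")
        assert c.answer_start == first


class TestPipelineInvariants:
    def test_inter_distances_within_bound(self):
        corpus = gen_corpus(SynthConfig(n_docs=15, seed=21))
        for doc in corpus.documents:
            split_sentences(doc)
            for c in extract_candidates(doc):
                if c.level == "inter":
                    assert 1 <= c.distance <= 3

    def test_inventory_matches_generator(self):
        corpus = gen_corpus(SynthConfig(n_docs=15, seed=22))
        expected = {(e.doc_id, e.head_id, e.tail_id): (e.level, e.label)
                    for e in corpus.inventory}
        got = {}
        for doc in corpus.documents:
            split_sentences(doc)
            for c in build_instances(doc):
                got[(c.doc_id, c.head_id, c.tail_id)] = (c.level, c.label)
        assert got == expected

    def test_positive_count_equals_reachable_gold(self):
        corpus = gen_corpus(SynthConfig(n_docs=15, seed=23))
        n_positive = sum(e.label for e in corpus.inventory)
        reachable = {(e.doc_id, e.head_id, e.tail_id)
                     for e in corpus.inventory}
        gold_reachable = corpus.all_gold() & reachable
        assert n_positive == len(gold_reachable)
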