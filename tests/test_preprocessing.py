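"""Segmentation determinism and BIO encode/decode identities."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from nodule_ie.preprocessing import (
    attach_surfaces,
    collapse_subtokens,
    decode_bio,
    encode_bio,
    expand_subtokens,
    normalize_and_segment,
    repair_bio,
    BIO_LABELS,
    X_TAG,
)
from nodule_ie.synth import GeneratorConfig, generate_corpus, make_worked_fixtures


class TestSegmentation:
    def test_two_sentence_report(self):
        tokens, sentences = normalize_and_segment("No pulmonary nodule. CT at 12 months.")
        assert len(sentences) == 2
        assert [t.surface for t in tokens] == [
            "No", "pulmonary", "nodule", ".", "CT", "at", "12", "months", ".",
        ]
        assert [t.sent_index for t in tokens] == [0, 0, 0, 0, 1, 1, 1, 1, 1]

    def test_worked_sentence_token_count(self):
        tokens, sentences = normalize_and_segment("nodule located at the lower lobe")
        assert len(sentences) == 1
        assert [t.surface for t in tokens] == ["nodule", "located", "at", "the", "lower", "lobe"]

    def test_single_token(self):
        tokens, sentences = normalize_and_segment("nodule")
        assert len(sentences) == 1
        assert (tokens[0].start, tokens[0].end) == (0, 6)

    def test_empty_text(self):
        tokens, sentences = normalize_and_segment("   ")
        assert tokens == [] and len(sentences) == 0

    def test_number_unit_splitting(self):
        tokens, _ = normalize_and_segment("4mm nodule")
        assert [t.surface for t in tokens][:2] == ["4", "mm"]

    def test_newline_and_header_break_sentences(self):
        tokens, sentences = normalize_and_segment("FINDINGS:\nThe lungs are clear.")
        assert len(sentences) == 2

    def test_offsets_index_original_text(self):
        text = "A 1.2 cm mass.\nStable."
        tokens, _ = normalize_and_segment(text)
        for t in tokens:
            assert text[t.start:t.end] == t.surface


class TestEncodeBio:
    def test_worked_example_tags(self):
        doc = make_worked_fixtures()[0]
        tokens, sentences = normalize_and_segment(doc.text)
        _, tags = encode_bio(doc, tokens, sentences)
        assert tags == [["B-Nodule", "O", "O", "O", "B-Site", "I-Site"]]

    def test_document_without_entities_is_all_O(self):
        doc = make_worked_fixtures()[7]  # "The lungs are clear."
        tokens, sentences = normalize_and_segment(doc.text)
        _, tags = encode_bio(doc, tokens, sentences)
        assert all(t == "O" for sent in tags for t in sent)

    def test_adjacent_same_category_entities_both_begin_with_B(self):
        doc = next(d for d in make_worked_fixtures() if d.doc_id == "worked_adjacent")
        tokens, sentences = normalize_and_segment(doc.text)
        _, tags = encode_bio(doc, tokens, sentences)
        flat = [t for sent in tags for t in sent]
        assert flat.count("B-Texture") == 2 and "I-Texture" not in flat


class TestDecodeBio:
    def test_inverse_of_encode_on_worked_example(self):
        doc = make_worked_fixtures()[0]
        tokens, sentences = normalize_and_segment(doc.text)
        sent_tokens, tags = encode_bio(doc, tokens, sentences)
        flat_tokens = [t for sent in sent_tokens for t in sent]
        flat_tags = [t for sent in tags for t in sent]
        decoded = attach_surfaces(decode_bio(flat_tags, flat_tokens), doc.text)
        assert [(e.category, e.start, e.end) for e in decoded] == [
            ("Nodule", 0, 6), ("Site", 22, 32),
        ]

    def test_orphan_I_promoted_to_entity(self):
        tokens, _ = normalize_and_segment("stable")
        decoded = decode_bio(["I-Size"], tokens)
        assert [(e.category, e.start, e.end) for e in decoded] == [("Size", 0, 6)]

    def test_all_O_decodes_to_nothing(self):
        tokens, _ = normalize_and_segment("The lungs are clear.")
        assert decode_bio(["O"] * len(tokens), tokens) == []

    def test_length_mismatch_raises(self):
        tokens, _ = normalize_and_segment("a b")
        with pytest.raises(ValueError):
            decode_bio(["O"], tokens)

    @given(
        st.lists(
            st.sampled_from(list(BIO_LABELS) + [X_TAG, "I-Bogus"]),
            min_size=1, max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_repair_totality_any_sequence_decodes(self, tags):
        text = " ".join(["tok"] * len(tags))
        tokens, _ = normalize_and_segment(text)
        decode_bio(tags, tokens)  # must not raise
        repaired = repair_bio(tags)
        # repaired sequences are well-formed: every I follows same-category B/I
        prev = None
        for t in repaired:
            if t.startswith("I-"):
                assert prev is not None and prev.endswith(t[2:])
            prev = t if t != "O" else None


class TestSubtokenTags:
    def test_expand_example(self):
        assert expand_subtokens(["B-Size"], [3]) == ["B-Size", X_TAG, X_TAG]

    def test_counts_of_one_are_identity(self):
        tags = ["B-Nodule", "O", "B-Site", "I-Site"]
        assert expand_subtokens(tags, [1] * 4) == tags

    def test_collapse_leading_label_rule(self):
        assert collapse_subtokens(["B-Site", X_TAG, "I-Site"], [2, 1]) == ["B-Site", "I-Site"]
        assert collapse_subtokens(["B-Nodule", X_TAG], [2]) == ["B-Nodule"]

    def test_leading_X_falls_back_to_O(self):
        assert collapse_subtokens([X_TAG, "B-Site"], [1, 1]) == ["O", "B-Site"]

    def test_zero_count_raises(self):
        with pytest.raises(ValueError):
            expand_subtokens(["O"], [0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            collapse_subtokens(["O", "O", "O"], [2, 2])

    def test_round_trip_random_sequences(self):
        rng = random.Random(13)
        for _ in range(100):
            n = rng.randint(1, 15)
            tags = [rng.choice(BIO_LABELS) for _ in range(n)]
            counts = [rng.randint(1, 4) for _ in range(n)]
            assert collapse_subtokens(expand_subtokens(tags, counts), counts) == tags


def test_encode_decode_identity_on_synthetic_corpus():
    """decode(encode(gold)) recovers the exact gold spans corpus-wide."""
    docs, _ = generate_corpus(GeneratorConfig(n_docs=100, seed=21))
    for doc in docs:
        tokens, sentences = normalize_and_segment(doc.text)
        sent_tokens, sent_tags = encode_bio(doc, tokens, sentences)
        flat_tokens = [t for s in sent_tokens for t in s]
        flat_tags = [t for s in sent_tags for t in s]
        decoded = attach_surfaces(decode_bio(flat_tags, flat_tokens), doc.text)
        assert {(e.category, e.start, e.end, e.surface) for e in decoded} == {
            (e.category, e.start, e.end, e.surface) for e in doc.entities
        }


def test_entity_spans_slice_to_surfaces_over_corpus():
    docs, _ = generate_corpus(GeneratorConfig(n_docs=200, seed=5))
    for doc in docs:
        for e in doc.entities:
            assert doc.text[e.start:e.end] == e.surface
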