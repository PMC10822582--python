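"""BIO encoding/decoding, token aggregation and the token link matrix."""

import numpy as np
import pytest

from fgie import (
    AnnotatedDocument,
    CONTEXT,
    EntityMention,
    PHENOTYPE,
    build_link_matrix,
    decode_bio,
    encode_bio,
    label_spaces,
)
from fgie.encoding import (
    CATEGORY_SPACE,
    aggregate_tokens_to_words,
    expand_word_labels_to_tokens,
)


def _mentions_key(mentions):
    return sorted((m.category, m.assertion, m.start, m.end) for m in mentions)


class TestEncode:
    def test_category_and_assertion_spaces_agree(self, example_doc, tokenizer):
        enc = encode_bio(example_doc, tokenizer)
        spaces = label_spaces()
        cat = enc.labels[CATEGORY_SPACE]
        # O in the category space implies O in all assertion spaces
        for i, c in enumerate(cat):
            if spaces[CATEGORY_SPACE].is_o(c):
                for head in example_doc.links[0].members:
                    assert spaces[head].is_o(enc.labels[head][i])

    def test_two_word_mention_has_b_then_i(self, tokenizer):
        text = "inhibited cell growth strongly"
        doc = AnnotatedDocument(
            "d", text,
            mentions=[EntityMention("p", PHENOTYPE, "cell growth", 10, 21,
                                    "cell growth")],
        )
        enc = encode_bio(doc, tokenizer)
        spaces = label_spaces()
        cat = [spaces[CATEGORY_SPACE].labels[i] for i in enc.labels[CATEGORY_SPACE]]
        assert cat == ["O", "B-Phenotype", "I-Phenotype", "O"]
        ph = [spaces[PHENOTYPE].labels[i] for i in enc.labels[PHENOTYPE]]
        assert ph == ["O", "B-cell growth", "I-cell growth", "O"]

    def test_adjacent_same_assertion_mentions_both_begin(self, tokenizer):
        text = "apoptosis apoptosis"
        doc = AnnotatedDocument(
            "d", text,
            mentions=[
                EntityMention("a", PHENOTYPE, "apoptosis", 0, 9, "apoptosis"),
                EntityMention("b", PHENOTYPE, "apoptosis", 10, 19, "apoptosis"),
            ],
        )
        enc = encode_bio(doc, tokenizer)
        space = label_spaces()[CATEGORY_SPACE]
        assert [space.labels[i] for i in enc.labels[CATEGORY_SPACE]] == [
            "B-Phenotype", "B-Phenotype",
        ]

    def test_document_without_mentions_is_all_o(self, tokenizer):
        doc = AnnotatedDocument("d", "nothing to see here")
        enc = encode_bio(doc, tokenizer)
        for seq in enc.labels.values():
            assert all(i == 0 for i in seq)


class TestDecode:
    def test_round_trip_worked_example(self, example_doc, tokenizer):
        enc = encode_bio(example_doc, tokenizer)
        back = decode_bio(enc.labels, enc.words, text=example_doc.text)
        assert _mentions_key(back) == _mentions_key(example_doc.mentions)

    def test_round_trip_synthetic_corpus(self, small_corpus, tokenizer):
        for doc in small_corpus:
            enc = encode_bio(doc, tokenizer)
            back = decode_bio(enc.labels, enc.words, text=doc.text)
            assert _mentions_key(back) == _mentions_key(doc.mentions)

    def test_orphan_inside_label_becomes_mention(self, tokenizer):
        doc = AnnotatedDocument("d", "one two three")
        enc = encode_bio(doc, tokenizer)
        spaces = label_spaces()
        labels = {name: list(seq) for name, seq in enc.labels.items()}
        labels[CATEGORY_SPACE][1] = spaces[CATEGORY_SPACE].i(CONTEXT)
        labels[CONTEXT][1] = spaces[CONTEXT].i("cells")
        out = decode_bio(labels, enc.words)
        assert len(out) == 1
        assert out[0].category == CONTEXT
        assert out[0].assertion == "cells"

    def test_majority_assertion_tie_takes_first_in_run(self, tokenizer):
        doc = AnnotatedDocument("d", "alpha beta")
        enc = encode_bio(doc, tokenizer)
        spaces = label_spaces()
        labels = {name: list(seq) for name, seq in enc.labels.items()}
        labels[CATEGORY_SPACE] = [
            spaces[CATEGORY_SPACE].b(CONTEXT), spaces[CATEGORY_SPACE].i(CONTEXT),
        ]
        labels[CONTEXT] = [spaces[CONTEXT].b("cells"),
                           spaces[CONTEXT].b("organism")]
        out = decode_bio(labels, enc.words)
        assert [m.assertion for m in out] == ["cells"]


class TestAggregation:
    def test_first_token_rule(self, tokenizer, example_doc):
        enc = encode_bio(example_doc, tokenizer)
        token_labels = expand_word_labels_to_tokens(enc)
        for name, word_seq in enc.labels.items():
            # word -> token copy then first-token aggregation is the identity
            assert aggregate_tokens_to_words(token_labels[name], enc) == word_seq

    def test_multi_token_word_takes_first(self, tokenizer):
        doc = AnnotatedDocument("d", "pseudohypoparathyroidism word")
        enc = encode_bio(doc, tokenizer)
        assert len(enc.token_ids[0]) > 1  # rare word splits into pieces
        seq = list(range(enc.n_tokens))
        assert aggregate_tokens_to_words(seq, enc)[0] == 0
        assert aggregate_tokens_to_words(seq, enc)[1] == len(enc.token_ids[0])


class TestLinkMatrix:
    def test_two_linked_single_token_mentions(self, tokenizer, example_doc):
        mat = build_link_matrix(
            example_doc, encode_bio(example_doc, tokenizer)
        )
        assert mat.shape[0] == mat.shape[1]
        assert np.all(np.tril(mat, -1) == 0)  # strictly upper triangular use

    def test_no_links_zero_matrix(self, tokenizer):
        doc = AnnotatedDocument("d", "nothing linked here")
        mat = build_link_matrix(doc, encode_bio(doc, tokenizer))
        assert mat.sum() == 0

    def test_worked_example_closure(self, tokenizer, example_doc):
        """Tokens of 'apoptosis' link to the perturbing action, 'induced' and
        the second 'PC cells' — but not to 'cell growth' (different group)."""
        enc = encode_bio(example_doc, tokenizer)
        mat = build_link_matrix(example_doc, enc)
        first = {mid: enc.mention_token_span(mid)[0] for mid, _ in
                 enc.mention_word_spans.items()}

        def linked(a, b):
            i, j = sorted((first[a], first[b]))
            return mat[i, j] == 1

        assert linked("p4", "pa")      # apoptosis - perturbing action
        assert linked("p4", "e2")      # apoptosis - induced
        assert linked("p4", "c2")      # apoptosis - second PC cells
        assert not linked("p4", "p1")  # apoptosis - cell growth
        assert not linked("p4", "e1")  # apoptosis - inhibit
        assert not linked("p4", "c1")  # apoptosis - first PC cells

    def test_within_mention_pairs_default_zero(self, tokenizer, example_doc):
        enc = encode_bio(example_doc, tokenizer)
        mat = build_link_matrix(example_doc, enc)
        t0, t1 = enc.mention_token_span("pa")
        assert mat[t0:t1, t0:t1].sum() == 0
        # opposite convention behind the flag
        mat2 = build_link_matrix(example_doc, enc, include_within_mention=True)
        assert mat2[t0:t1, t0:t1].sum() > 0
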