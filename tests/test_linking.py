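"""Linking model: pair enumeration, forward contract, training, prediction."""

import math

import numpy as np
import pytest

from fgie import SynthConfig, generate_corpus
from fgie.encoding import build_link_matrix, encode_bio
from fgie.encoders import FrozenRandomEncoder, TinyTransformerEncoder
from fgie.linking import (
    LinkingModel,
    LinkTrainConfig,
    PairBatch,
    enumerate_pairs,
    link_forward,
    linking_loss,
    predict_links,
    train_linker,
)
from fgie.nn import Adam, Tensor


class TestEnumeratePairs:
    def test_all_mode_counts(self, tokenizer):
        from fgie import AnnotatedDocument

        doc = AnnotatedDocument("d", "a b c d")
        enc = encode_bio(doc, tokenizer)
        assert enc.n_tokens == 4
        mat = build_link_matrix(doc, enc)
        pairs = enumerate_pairs(enc, mat, mode="all")
        assert len(pairs) == 10  # 4*5/2
        assert np.all(pairs.i <= pairs.j)

    def test_tagged_only_restricts_to_mention_tokens(self, tokenizer,
                                                     example_doc):
        enc = encode_bio(example_doc, tokenizer)
        mat = build_link_matrix(example_doc, enc)
        pairs = enumerate_pairs(enc, mat, mode="tagged-only")
        tagged = set()
        for mid in enc.mention_word_spans:
            t0, t1 = enc.mention_token_span(mid)
            tagged.update(range(t0, t1))
        m = len(tagged)
        assert len(pairs) == m * (m + 1) // 2  # exhaustive: asserted by count
        assert set(pairs.i) | set(pairs.j) <= tagged

    def test_negative_cap_keeps_all_positives(self, tokenizer, example_doc):
        enc = encode_bio(example_doc, tokenizer)
        mat = build_link_matrix(example_doc, enc)
        full = enumerate_pairs(enc, mat, mode="tagged-only")
        capped = enumerate_pairs(enc, mat, mode="tagged-only",
                                 negative_cap=1.0,
                                 rng=np.random.default_rng(0))
        n_pos = int(full.link.sum())
        assert int(capped.link.sum()) == n_pos
        assert len(capped) - n_pos <= n_pos

    def test_sametag_bits_mark_within_mention_pairs(self, tokenizer,
                                                    example_doc):
        enc = encode_bio(example_doc, tokenizer)
        mat = build_link_matrix(example_doc, enc)
        pairs = enumerate_pairs(enc, mat, mode="tagged-only")
        t0, t1 = enc.mention_token_span("pa")
        for i, j, same in zip(pairs.i, pairs.j, pairs.sametag):
            if t0 <= i < t1 and t0 <= j < t1:
                assert same == 1


class TestLinkForward:
    def test_pair_features_are_concatenated_embeddings(self, tokenizer):
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=4, seed=1)
        model = LinkingModel(enc, tokenizer)
        emb = enc.embed(np.array([3, 9]))
        batch = PairBatch(i=np.array([0]), j=np.array([1]),
                          link=np.array([0]), sametag=np.array([0]))
        logits, _ = link_forward(model, emb, batch)
        feats = np.concatenate([emb.data[0], emb.data[1]])
        by_hand = feats @ model.link_head.W.data + model.link_head.b.data
        assert np.allclose(logits.data[0], by_hand)

    def test_zero_init_heads_give_half_probability(self, tokenizer):
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=4, seed=1)
        model = LinkingModel(enc, tokenizer)
        model.link_head.W.data[:] = 0.0
        model.link_head.b.data[:] = 0.0
        emb = enc.embed(np.array([1, 2, 3]))
        batch = PairBatch(i=np.array([0, 0]), j=np.array([1, 2]),
                          link=np.zeros(2, dtype=np.int8),
                          sametag=np.zeros(2, dtype=np.int8))
        logits, _ = link_forward(model, emb, batch)
        assert np.allclose(logits.softmax(axis=-1).data, 0.5)

    def test_dimension_mismatch_rejected(self, tokenizer):
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=4, seed=1)
        model = LinkingModel(enc, tokenizer)
        bad = Tensor(np.zeros((3, 7)))
        batch = PairBatch(i=np.array([0]), j=np.array([1]),
                          link=np.array([0]), sametag=np.array([0]))
        with pytest.raises(ValueError, match="dim"):
            link_forward(model, bad, batch)


class TestLinkingLoss:
    def _batch(self, link, same):
        n = len(link)
        return PairBatch(i=np.zeros(n, dtype=int), j=np.ones(n, dtype=int),
                         link=np.array(link), sametag=np.array(same))

    def test_half_probability_costs_ln2_per_head(self):
        n = 6
        zeros = Tensor(np.zeros((n, 2)))
        batch = self._batch([0, 1] * 3, [1, 0] * 3)
        loss = linking_loss(zeros, zeros, batch, pos_weight=1.0, aux_lambda=1.0)
        assert loss.item() == pytest.approx(2 * math.log(2))

    def test_perfect_predictions_cost_zero(self):
        link = np.array([0, 1, 1])
        same = np.array([1, 0, 0])
        link_logits = Tensor(np.eye(2)[link] * 1e4)
        same_logits = Tensor(np.eye(2)[same] * 1e4)
        loss = linking_loss(link_logits, same_logits, self._batch(link, same))
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_pos_weight_scales_positive_contribution(self):
        rng = np.random.default_rng(0)
        link = np.array([0, 1, 0, 1])
        logits = Tensor(rng.normal(size=(4, 2)))
        batch = self._batch(link, [0, 0, 0, 0])
        l1 = linking_loss(logits, logits, batch, pos_weight=1.0, aux_lambda=0.0)
        l2 = linking_loss(logits, logits, batch, pos_weight=2.0, aux_lambda=0.0)
        logp = logits.log_softmax(axis=-1).data
        pos_share = -(logp[np.arange(4), link])[link == 1].sum() / 4
        assert l2.item() - l1.item() == pytest.approx(pos_share)


@pytest.fixture(scope="module")
def tiny_run():
    corpus = generate_corpus(SynthConfig(n_docs=25, seed=5))
    config = LinkTrainConfig(epochs=3, seed=0, encoder_dim=32, encoder_ff=64)
    model, history = train_linker(corpus, config)
    return corpus, config, model, history


class TestTraining:
    def test_loss_decreases(self, tiny_run):
        _, _, _, history = tiny_run
        assert history[-1] < history[0]

    def test_seeded_rerun_identical(self, tiny_run):
        corpus, config, _, history = tiny_run
        _, again = train_linker(corpus, config)
        assert again == history

    def test_auxiliary_off_still_trains(self):
        corpus = generate_corpus(SynthConfig(n_docs=10, seed=6))
        config = LinkTrainConfig(epochs=2, seed=0, encoder_dim=32,
                                 encoder_ff=64, aux_lambda=0.0)
        _, history = train_linker(corpus, config)
        assert len(history) == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_linker([])


class TestPredictLinks:
    def test_all_zero_probabilities_empty_set(self, tokenizer, example_doc):
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=4, seed=2)
        model = LinkingModel(enc, tokenizer)
        # force the positive-class logit far down
        model.link_head.W.data[:] = 0.0
        model.link_head.b.data[:] = [1e4, -1e4]
        assert predict_links(model, example_doc) == set()

    def test_oracle_head_recovers_gold_closure(self, tokenizer, example_doc,
                                               monkeypatch):
        """A link head that echoes the gold token matrix yields exactly the
        entity-pair closure of the link groups."""
        enc_doc = encode_bio(example_doc, tokenizer)
        gold_matrix = build_link_matrix(example_doc, enc_doc)
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=4, seed=2)
        model = LinkingModel(enc, tokenizer)

        import fgie.linking as linking_mod

        def fake_forward(mdl, emb, batch):
            probs = gold_matrix[batch.i, batch.j].astype(float)
            logits = np.stack([1 - probs, probs], axis=-1) * 1e4
            return Tensor(logits), Tensor(logits)

        monkeypatch.setattr(linking_mod, "link_forward", fake_forward)
        pairs = linking_mod.predict_links(model, example_doc)
        assert pairs == example_doc.linked_pairs()

    def test_worked_example_specific_pairs(self, tokenizer, example_doc):
        gold = example_doc.linked_pairs()
        assert frozenset(("p4", "pa")) in gold
        assert frozenset(("p4", "e2")) in gold
        assert frozenset(("p4", "c2")) in gold
        assert frozenset(("p4", "p2")) not in gold  # apoptosis-colony formation
        assert len(gold) == 18

    def test_output_pairs_are_unordered_and_no_self(self, tiny_linker,
                                                    small_corpus):
        pairs = predict_links(tiny_linker, small_corpus[0])
        for p in pairs:
            assert len(p) == 2


class TestLinearProbe:
    def test_link_head_fits_separable_structure(self, tokenizer):
        """Frozen random encoder + linearly separable link rule: the link
        head alone reaches perfect training accuracy."""
        rng = np.random.default_rng(7)
        enc = FrozenRandomEncoder(tokenizer.vocab_size, dim=8, seed=7)
        model = LinkingModel(enc, tokenizer)
        ids = rng.integers(2, tokenizer.vocab_size, 30)
        emb = enc.embed(ids)
        i, j = np.triu_indices(30)
        true_w = rng.normal(size=16)
        feats = np.concatenate([emb.data[i], emb.data[j]], axis=-1)
        bits = (feats @ true_w > 0).astype(np.int8)
        batch = PairBatch(i=i, j=j, link=bits, sametag=bits)
        opt = Adam(model.link_head.parameters(), lr=0.05)
        for _ in range(400):
            opt.zero_grad()
            logits, _ = link_forward(model, emb, batch)
            linking_loss(logits, logits, batch, aux_lambda=0.0).backward()
            opt.step()
        logits, _ = link_forward(model, emb, batch)
        pred = logits.data.argmax(axis=-1)
        assert (pred == bits).mean() == 1.0
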