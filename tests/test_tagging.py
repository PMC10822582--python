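"""Tagging model: loss weights, forward contract, training, prediction."""

import numpy as np
import pytest

from fgie import SynthConfig, generate_corpus
from fgie.encoding import (
    CATEGORY_SPACE,
    encode_bio,
    expand_word_labels_to_tokens,
    label_spaces,
)
from fgie.encoders import TinyTransformerEncoder
from fgie.nn import Tensor
from fgie.tagging import (
    TaggingModel,
    TrainConfig,
    compute_loss_weights,
    predict,
    tagging_loss,
    train_tagger,
)


class TestLossWeights:
    def test_inverse_frequency_closed_form(self):
        counts = {"s": np.array([900.0, 50.0, 50.0])}
        w = compute_loss_weights(counts, exponent=1.0)["s"]
        raw = np.array([1000 / 900, 1000 / 50, 1000 / 50])
        assert np.allclose(w, raw / raw.mean())
        assert w.mean() == pytest.approx(1.0)

    def test_exponent_zero_is_unit_weights(self):
        counts = {"s": np.array([900.0, 50.0, 1.0])}
        assert np.allclose(compute_loss_weights(counts, 0.0)["s"], 1.0)

    @pytest.mark.parametrize("exponent", [0.25, 0.5, 1.0])
    def test_rarer_class_never_lighter(self, exponent):
        rng = np.random.default_rng(0)
        counts = {"s": rng.integers(1, 1000, size=12).astype(float)}
        w = compute_loss_weights(counts, exponent)["s"]
        order = np.argsort(counts["s"])
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_zero_count_class_gets_max_weight(self):
        counts = {"s": np.array([100.0, 10.0, 0.0])}
        w = compute_loss_weights(counts, 1.0)["s"]
        assert w[2] == pytest.approx(w[1])

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="zero"):
            compute_loss_weights({"s": np.zeros(3)}, 1.0)


class TestForward:
    def test_distributions_sum_to_one(self, tokenizer):
        enc = TinyTransformerEncoder(tokenizer.vocab_size, dim=16, n_layers=1,
                                     n_heads=2, d_ff=32, seed=0)
        model = TaggingModel(enc, tokenizer)
        probs = model.forward(np.arange(12) % tokenizer.vocab_size)
        spaces = label_spaces()
        for name, p in probs.items():
            assert p.shape == (12, spaces[name].size)
            assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
            assert (p >= 0).all()

    def test_doubling_class_weight_doubles_its_contribution(self, tokenizer):
        rng = np.random.default_rng(2)
        logits = {"s": Tensor(rng.normal(size=(6, 3)))}
        gold = {"s": np.array([0, 1, 1, 2, 0, 1])}
        w1 = {"s": np.array([1.0, 1.0, 1.0])}
        w2 = {"s": np.array([1.0, 2.0, 1.0])}
        base = tagging_loss(logits, gold, w1).item()
        boosted = tagging_loss(logits, gold, w2).item()
        # hand-summed oracle: the delta equals the class-1 tokens' unweighted share
        logp = logits["s"].log_softmax(axis=-1).data
        class1 = -(logp[np.arange(6), gold["s"]])[gold["s"] == 1].sum() / 6
        assert boosted - base == pytest.approx(class1)

    def test_perfect_predictions_zero_loss(self):
        y = np.array([0, 2, 1])
        logits = {"s": Tensor(np.eye(3)[y] * 1e4)}
        assert tagging_loss(logits, {"s": y}).item() == pytest.approx(0.0, abs=1e-6)


@pytest.fixture(scope="module")
def tiny_run():
    corpus = generate_corpus(SynthConfig(n_docs=25, seed=3))
    config = TrainConfig(epochs=3, seed=0, encoder_dim=32, encoder_ff=64)
    model, history = train_tagger(corpus, config)
    return corpus, config, model, history


class TestTraining:
    def test_loss_decreases(self, tiny_run):
        _, _, _, history = tiny_run
        assert history[-1] < history[0]

    def test_seeded_rerun_reproduces_history(self, tiny_run):
        corpus, config, _, history = tiny_run
        _, again = train_tagger(corpus, config)
        assert again == history

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_tagger([], TrainConfig())

    def test_category_head_ablation_trains_and_predicts(self):
        corpus = generate_corpus(SynthConfig(n_docs=10, seed=4))
        config = TrainConfig(epochs=2, seed=0, encoder_dim=32, encoder_ff=64,
                             include_category_head=False)
        model, history = train_tagger(corpus, config)
        assert CATEGORY_SPACE not in model.heads
        doc = predict(model, corpus[0].text)
        from fgie import validate

        assert validate(doc) == []


class TestPredict:
    def test_empty_text_yields_no_mentions(self, tiny_tagger):
        assert predict(tiny_tagger, "").mentions == []

    def test_gold_faking_model_recovers_gold_mentions(self, tokenizer,
                                                      small_corpus,
                                                      monkeypatch):
        """If the heads emit one-hot gold labels, the prediction pipeline
        (tokenize -> forward -> first-token aggregation -> BIO decode) is
        the identity on the gold mentions."""
        doc = small_corpus[0]
        enc = TinyTransformerEncoder(tokenizer.vocab_size, dim=8, n_layers=1,
                                     n_heads=1, d_ff=8, seed=0)
        model = TaggingModel(enc, tokenizer)
        gold_enc = encode_bio(doc, tokenizer)
        gold_tokens = expand_word_labels_to_tokens(gold_enc)
        spaces = label_spaces()

        def fake_forward(token_ids):
            out = {}
            for name, seq in gold_tokens.items():
                onehot = np.zeros((len(seq), spaces[name].size))
                onehot[np.arange(len(seq)), seq] = 1.0
                out[name] = onehot
            return out

        monkeypatch.setattr(model, "forward", fake_forward)
        result = predict(model, doc.text, doc_id=doc.doc_id)
        got = sorted((m.category, m.assertion, m.start, m.end)
                     for m in result.mentions)
        want = sorted((m.category, m.assertion, m.start, m.end)
                      for m in doc.mentions)
        assert got == want

    def test_trained_model_emits_schema_mentions(self, tiny_tagger,
                                                 small_corpus):
        from fgie import DEFAULT_SCHEMA

        doc = predict(tiny_tagger, small_corpus[-1].text)
        for m in doc.mentions:
            assert DEFAULT_SCHEMA.is_valid(m.category, m.assertion)
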