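"""Splits, P/R/F1 counting rules, baseline, cross-validation driver."""

import numpy as np
import pytest

from fgie import (
    MetricsReport,
    SynthConfig,
    cooccurrence_baseline,
    crossval,
    entity_pair_candidates,
    generate_corpus,
    linking_prf,
    make_splits,
    tagging_prf,
)
from fgie.evaluation import corpus_linking_prf, mean_reports


def brute_force_tagging_counts(pred, gold, o_label=0):
    """Independent recount with explicit loops, including the rule that a
    non-O/non-O mismatch contributes both a false positive and a false
    negative."""
    tp = fp = fn = 0
    for k in range(len(gold)):
        p, g = pred[k], gold[k]
        if p == g and g != o_label:
            tp += 1
        if p != g and p != o_label:
            fp += 1
        if p != g and g != o_label:
            fn += 1
    return tp, fp, fn


class TestTaggingPrf:
    def test_all_correct_non_o(self):
        labels = [1, 2, 3, 1, 2, 3, 4, 5, 6, 7]
        r = tagging_prf(labels, labels)
        assert (r.tp, r.fp, r.fn) == (10, 0, 0)
        assert r.f1 == 1.0

    def test_label_swap_counts_fp_and_fn(self):
        # gold B-Context predicted B-Phenotype: both non-O
        r = tagging_prf([2], [1])
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_all_o_everywhere_is_degenerate_zero(self):
        r = tagging_prf([0, 0, 0], [0, 0, 0])
        assert (r.tp, r.fp, r.fn) == (0, 0, 0)
        assert r.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tagging_prf([0], [0, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(2, 6))
            pred = rng.integers(0, k, n).tolist()
            gold = rng.integers(0, k, n).tolist()
            r = tagging_prf(pred, gold)
            assert (r.tp, r.fp, r.fn) == brute_force_tagging_counts(pred, gold)


class TestLinkingPrf:
    def test_perfect_prediction(self, example_doc):
        gold = example_doc.linked_pairs()
        cand = entity_pair_candidates(example_doc)
        r = linking_prf(gold, gold, cand)
        assert r.f1 == 1.0

    def test_predict_everything_on_worked_example(self, example_doc):
        cand = entity_pair_candidates(example_doc)
        gold = example_doc.linked_pairs()
        assert (len(cand), len(gold)) == (36, 18)
        r = linking_prf(cand, gold, cand)
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(1.0)
        assert r.f1 == pytest.approx(2 / 3)

    def test_empty_prediction_convention(self, example_doc):
        cand = entity_pair_candidates(example_doc)
        r = linking_prf(set(), example_doc.linked_pairs(), cand)
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_pair_outside_candidates_rejected(self, example_doc):
        cand = entity_pair_candidates(example_doc)
        with pytest.raises(ValueError, match="outside"):
            linking_prf({frozenset(("ghost", "pa"))},
                        example_doc.linked_pairs(), cand)


class TestBaseline:
    def test_single_sentence_predicts_all_pairs(self, example_doc):
        assert len(cooccurrence_baseline(example_doc)) == 36

    def test_cross_sentence_entities_not_paired(self, tokenizer):
        from fgie import AnnotatedDocument, EntityMention, PHENOTYPE

        text = "We saw apoptosis. Then necrosis."
        doc = AnnotatedDocument(
            "d", text,
            mentions=[
                EntityMention("a", PHENOTYPE, "apoptosis", 7, 16, "apoptosis"),
                EntityMention("b", PHENOTYPE, "necrosis", 23, 31, "necrosis"),
            ],
        )
        assert cooccurrence_baseline(doc) == set()

    def test_recall_one_when_groups_are_single_sentence(self):
        docs = generate_corpus(SynthConfig(n_docs=30, seed=9,
                                           p_multisentence=0.0))
        r = corpus_linking_prf(docs, cooccurrence_baseline)
        assert r.recall == 1.0

    def test_cross_sentence_links_lower_recall(self):
        docs = generate_corpus(SynthConfig(n_docs=30, seed=9,
                                           p_multisentence=1.0))
        r = corpus_linking_prf(docs, cooccurrence_baseline)
        assert r.recall < 1.0

    def test_metrics_invariant_under_document_order(self):
        docs = generate_corpus(SynthConfig(n_docs=20, seed=10))
        r1 = corpus_linking_prf(docs, cooccurrence_baseline)
        r2 = corpus_linking_prf(list(reversed(docs)), cooccurrence_baseline)
        assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn)


class TestSplits:
    def test_sizes_and_disjointness(self):
        corpus = generate_corpus(SynthConfig(n_docs=100, seed=1))
        plan = make_splits(corpus, seed=0)
        assert len(plan.holdout) == 10
        sizes = sorted(len(f) for f in plan.folds)
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 90
        everything = set(plan.holdout)
        for f in plan.folds:
            assert everything.isdisjoint(f)
            everything.update(f)
        assert everything == set(range(100))

    def test_deterministic_under_seed(self):
        corpus = generate_corpus(SynthConfig(n_docs=40, seed=1))
        a, b = make_splits(corpus, seed=5), make_splits(corpus, seed=5)
        assert a == b

    def test_too_few_documents(self):
        corpus = generate_corpus(SynthConfig(n_docs=3, seed=1))
        with pytest.raises(ValueError, match="at least"):
            make_splits(corpus, seed=0)


class TestCrossval:
    def test_gold_echo_model_scores_one_everywhere(self):
        corpus = generate_corpus(SynthConfig(n_docs=24, seed=2))

        def train_fn(train_docs):
            return {d.doc_id: d for d in corpus}  # "model" echoing gold

        def eval_fn(model, test_docs):
            report = MetricsReport()
            for doc in test_docs:
                gold = doc.linked_pairs()
                pred = model[doc.doc_id].linked_pairs()
                report = report + linking_prf(
                    pred, gold, entity_pair_candidates(doc)
                )
            return {"linking": report}

        result = crossval(corpus, train_fn, eval_fn, seed=0)
        for fold_report in result["folds"]:
            assert fold_report["linking"].f1 == 1.0
        assert result["mean"]["linking"]["f1"] == pytest.approx(1.0)

    def test_mean_is_arithmetic_mean_of_folds(self):
        reports = [
            {"h": MetricsReport(tp=3, fp=1, fn=0)},
            {"h": MetricsReport(tp=1, fp=1, fn=2)},
        ]
        mean = mean_reports(reports)
        f1s = [r["h"].f1 for r in reports]
        assert mean["h"]["f1"] == pytest.approx(sum(f1s) / 2, abs=1e-12)
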