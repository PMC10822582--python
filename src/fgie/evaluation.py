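"""Evaluation protocol: splits, tagging/linking P/R/F1, co-occurrence baseline.

Tagging is scored per word after first-token aggregation, micro-averaged
over each head's classes with the following counting rule. For each word:

* prediction equals the gold label and the gold label is not ``O`` — TP;
* the prediction is wrong and is not ``O`` — FP;
* the prediction is wrong and the *gold* label is not ``O`` — FN.

A non-``O``/non-``O`` mismatch therefore counts as **both** a FP and a
FN; precision divides by TP+FP and recall by TP+FN, so the double count
is handled consistently.

Linking is scored over the exhaustive candidate set of unordered pairs
of distinct tagged mentions: TP = predicted and gold-linked, FP =
predicted only, FN = gold-linked only. The co-occurrence baseline
predicts every pair of mentions whose spans share a sentence, mapped
onto the same candidate-pair space as the model so its F1 is
commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .documents import AnnotatedDocument
from .segment import SentenceSplitter, split_sentences

__all__ = [
    "MetricsReport",
    "SplitPlan",
    "make_splits",
    "tagging_prf",
    "linking_prf",
    "entity_pair_candidates",
    "cooccurrence_baseline",
    "crossval",
    "mean_reports",
]


@dataclass
class MetricsReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "MetricsReport") -> "MetricsReport":
        return MetricsReport(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class SplitPlan:
    """10% document-level holdout plus k disjoint folds over the remainder."""

    holdout: list[int]
    folds: list[list[int]]
    seed: int

    def train_indices(self, fold: int) -> list[int]:
        return [i for f, fold_ids in enumerate(self.folds) if f != fold
                for i in fold_ids]


def make_splits(
    corpus: Sequence[AnnotatedDocument], seed: int, k: int = 4,
    holdout_fraction: float = 0.10,
) -> SplitPlan:
    n = len(corpus)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} documents, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_holdout = int(round(holdout_fraction * n))
    holdout = sorted(order[:n_holdout].tolist())
    rest = order[n_holdout:]
    folds = [sorted(rest[f::k].tolist()) for f in range(k)]
    return SplitPlan(holdout=holdout, folds=folds, seed=seed)


def tagging_prf(
    pred: Sequence[int], gold: Sequence[int], o_label: int = 0
) -> MetricsReport:
    """Word-level counts with the FP+FN double-count rule for label swaps."""
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} pred vs {len(gold)} gold")
    report = MetricsReport()
    for p, g in zip(pred, gold):
        if p == g:
            if g != o_label:
                report.tp += 1
        else:
            if p != o_label:
                report.fp += 1
            if g != o_label:
                report.fn += 1
    return report


def linking_prf(
    pred: set[frozenset[str]],
    gold: set[frozenset[str]],
    candidates: set[frozenset[str]],
) -> MetricsReport:
    """Set-arithmetic counts over the exhaustive candidate-pair space."""
    for name, pairs in (("pred", pred), ("gold", gold)):
        extra = pairs - candidates
        if extra:
            raise ValueError(f"{name} contains pairs outside candidates: {extra}")
    return MetricsReport(
        tp=len(pred & gold), fp=len(pred - gold), fn=len(gold - pred)
    )


def entity_pair_candidates(doc: AnnotatedDocument) -> set[frozenset[str]]:
    """All unordered pairs of distinct mentions in one document."""
    ids = [m.id for m in doc.mentions]
    return {
        frozenset((ids[a], ids[b]))
        for a in range(len(ids))
        for b in range(a + 1, len(ids))
    }


def cooccurrence_baseline(
    doc: AnnotatedDocument,
    sentence_splitter: SentenceSplitter = split_sentences,
) -> set[frozenset[str]]:
    """Predict a link for every mention pair whose spans share a sentence.

    A mention belongs to the sentence containing its start offset.
    """
    sentences = sentence_splitter(doc.text)

    def sentence_of(pos: int) -> int:
        for s, (a, b) in enumerate(sentences):
            if a <= pos < b:
                return s
        return len(sentences) - 1

    by_sentence: dict[int, list[str]] = {}
    for m in doc.mentions:
        by_sentence.setdefault(sentence_of(m.start), []).append(m.id)
    out: set[frozenset[str]] = set()
    for ids in by_sentence.values():
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                out.add(frozenset((ids[a], ids[b])))
    return out


def corpus_linking_prf(
    docs: Iterable[AnnotatedDocument],
    predict_pairs: Callable[[AnnotatedDocument], set[frozenset[str]]],
) -> MetricsReport:
    """Micro-averaged linking P/R/F1 of a per-document pair predictor."""
    total = MetricsReport()
    for doc in docs:
        candidates = entity_pair_candidates(doc)
        gold = doc.linked_pairs()
        pred = predict_pairs(doc)
        total = total + linking_prf(pred, gold, candidates)
    return total


def crossval(
    corpus: Sequence[AnnotatedDocument],
    train_fn: Callable[[list[AnnotatedDocument]], object],
    eval_fn: Callable[[object, list[AnnotatedDocument]], dict[str, MetricsReport]],
    seed: int = 0,
    k: int = 4,
) -> dict:
    """k-fold cross-validation plus a separately reported holdout score.

    ``train_fn`` fits a model on a training corpus; ``eval_fn`` returns a
    per-head :class:`MetricsReport` dict on a test corpus. Fold scores are
    averaged per head; the holdout is scored by a model trained on all
    non-holdout documents.
    """
    plan = make_splits(corpus, seed=seed, k=k)
    fold_reports: list[dict[str, MetricsReport]] = []
    for fold in range(k):
        train_docs = [corpus[i] for i in plan.train_indices(fold)]
        test_docs = [corpus[i] for i in plan.folds[fold]]
        model = train_fn(train_docs)
        fold_reports.append(eval_fn(model, test_docs))
    non_holdout = [corpus[i] for f in plan.folds for i in f]
    final_model = train_fn(non_holdout)
    holdout_report = eval_fn(final_model, [corpus[i] for i in plan.holdout])
    return {
        "folds": fold_reports,
        "mean": mean_reports(fold_reports),
        "holdout": {h: r.as_dict() for h, r in holdout_report.items()},
        "plan": plan,
    }


def mean_reports(
    fold_reports: list[dict[str, MetricsReport]],
) -> dict[str, dict[str, float]]:
    """Per-head arithmetic mean of precision/recall/F1 across folds."""
    heads = fold_reports[0].keys()
    out: dict[str, dict[str, float]] = {}
    for h in heads:
        out[h] = {
            metric: float(
                np.mean([getattr(fr[h], metric) for fr in fold_reports])
            )
            for metric in ("precision", "recall", "f1")
        }
    return out
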