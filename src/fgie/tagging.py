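"""The NER tagging model.

A shared encoder produces one embedding per sub-word token; five linear
softmax heads read it: a *category* head over the four entity categories
(BIO-encoded) and four *assertion* heads, one per category, over that
category's assertion vocabulary (BIO-encoded). All five heads are
trained jointly with class-weighted cross-entropy; the category head is
auxiliary at decode time in the sense that mentions are segmented from
its output while the assertion comes from the matching assertion head,
but it demonstrably aids the shared encoder.

Class imbalance (the vast majority of tokens are ``O``) is handled by
inverse-frequency loss weights: ``weight(c) ∝ (total / count(c)) **
exponent``, normalised to mean 1 within each label space; exponent 0
turns balancing off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .documents import AnnotatedDocument
from .encoding import (
    CATEGORY_SPACE,
    EncodedDocument,
    aggregate_tokens_to_words,
    decode_bio,
    encode_bio,
    expand_word_labels_to_tokens,
    label_spaces,
)
from .encoders import EncoderContract, TinyTransformerEncoder, windows
from .nn import Adam, Linear, Tensor
from .schema import DEFAULT_SCHEMA, Schema
from .segment import segment_words
from .subword import SubwordTokenizer, TrainedVocabTokenizer

__all__ = [
    "TrainConfig",
    "TaggingModel",
    "compute_loss_weights",
    "tagging_loss",
    "train_tagger",
    "predict",
]


@dataclass
class TrainConfig:
    """Hyperparameters for desk-scale training (all declared defaults)."""

    epochs: int = 12
    learning_rate: float = 1e-3
    seed: int = 0
    encoder_dim: int = 64
    encoder_layers: int = 2
    encoder_heads: int = 2
    encoder_ff: int = 128
    window: int = 512
    window_overlap: int = 64
    loss_weight_exponent: float = 0.5
    include_category_head: bool = True
    min_word_count: int = 2

    def to_dict(self) -> dict:
        return asdict(self)


class TaggingModel:
    """Shared encoder + five linear softmax heads (one per label space)."""

    def __init__(
        self,
        encoder: EncoderContract,
        tokenizer: SubwordTokenizer,
        schema: Schema = DEFAULT_SCHEMA,
        seed: int = 0,
        include_category_head: bool = True,
    ):
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.schema = schema
        self.spaces = label_spaces(schema)
        self.include_category_head = include_category_head
        rng = np.random.default_rng(seed + 1)
        self.heads: dict[str, Linear] = {
            name: Linear(encoder.dim, space.size, rng)
            for name, space in self.spaces.items()
            if include_category_head or name != CATEGORY_SPACE
        }

    def head_names(self) -> list[str]:
        return list(self.heads)

    def parameters(self) -> list[Tensor]:
        params = list(self.encoder.parameters())
        for head in self.heads.values():
            params += head.parameters()
        return params

    def forward_logits(self, token_ids: np.ndarray) -> dict[str, Tensor]:
        emb = self.encoder.embed(token_ids)
        return {name: head(emb) for name, head in self.heads.items()}

    def forward(self, token_ids: np.ndarray) -> dict[str, np.ndarray]:
        """Per-token probability distributions for each head."""
        return {
            name: logits.softmax(axis=-1).data
            for name, logits in self.forward_logits(token_ids).items()
        }


def compute_loss_weights(
    counts: dict[str, np.ndarray], exponent: float
) -> dict[str, np.ndarray]:
    """Inverse-frequency class weights, normalised to mean 1 per space.

    Classes never observed receive the maximum weight observed in their
    space (they are rare by definition). ``exponent=0`` yields unit
    weights; weights are monotone non-increasing in class frequency.
    """
    weights: dict[str, np.ndarray] = {}
    for name, c in counts.items():
        c = np.asarray(c, dtype=np.float64)
        total = c.sum()
        if total == 0:
            raise ValueError(f"label space {name!r}: all class counts are zero")
        w = np.zeros_like(c)
        nz = c > 0
        w[nz] = (total / c[nz]) ** exponent
        if (~nz).any():
            w[~nz] = w[nz].max()
        weights[name] = w / w.mean()
    return weights


def tagging_loss(
    logits: dict[str, Tensor],
    gold: dict[str, Sequence[int]],
    weights: dict[str, np.ndarray] | None = None,
) -> Tensor:
    """Sum over heads of class-weighted token-level cross-entropy.

    Normalised per token within each head, so uniform predictions over a
    k-class head cost ln(k) per token with unit weights.
    """
    total: Tensor | None = None
    for name, head_logits in logits.items():
        y = np.asarray(gold[name], dtype=np.intp)
        n = len(y)
        logp = head_logits.log_softmax(axis=-1)
        onehot = np.zeros(head_logits.shape)
        onehot[np.arange(n), y] = 1.0
        nll = -(logp * Tensor(onehot)).sum(axis=-1)
        if weights is not None:
            w = weights[name][y]
            head_loss = (nll * Tensor(w)).sum() * (1.0 / n)
        else:
            head_loss = nll.sum() * (1.0 / n)
        total = head_loss if total is None else total + head_loss
    assert total is not None
    return total


def _corpus_label_counts(
    encoded: list[EncodedDocument], spaces, head_names
) -> dict[str, np.ndarray]:
    counts = {name: np.zeros(spaces[name].size) for name in head_names}
    for enc in encoded:
        token_labels = expand_word_labels_to_tokens(enc)
        for name in head_names:
            np.add.at(counts[name], token_labels[name], 1)
    return counts


def train_tagger(
    corpus: list[AnnotatedDocument],
    config: TrainConfig = TrainConfig(),
    tokenizer: SubwordTokenizer | None = None,
    schema: Schema = DEFAULT_SCHEMA,
) -> tuple[TaggingModel, list[float]]:
    """Train the tagger on gold-annotated documents.

    Returns the model and the per-epoch mean training loss. Fixed seed
    (config + tokenizer) reproduces the history exactly on one device.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    if tokenizer is None:
        words = [w.surface for doc in corpus for w in segment_words(doc.text)]
        tokenizer = TrainedVocabTokenizer.train(words, config.min_word_count)
    encoder = TinyTransformerEncoder(
        vocab_size=tokenizer.vocab_size,
        dim=config.encoder_dim,
        n_layers=config.encoder_layers,
        n_heads=config.encoder_heads,
        d_ff=config.encoder_ff,
        max_len=config.window,
        seed=config.seed,
    )
    model = TaggingModel(
        encoder, tokenizer, schema, seed=config.seed,
        include_category_head=config.include_category_head,
    )
    encoded = [encode_bio(doc, tokenizer, schema) for doc in corpus]
    counts = _corpus_label_counts(encoded, model.spaces, model.head_names())
    weights = compute_loss_weights(counts, config.loss_weight_exponent)

    optim = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    docs = [
        (np.asarray(e.flat_token_ids), expand_word_labels_to_tokens(e))
        for e in encoded
        if e.n_tokens > 0
    ]
    for _ in range(config.epochs):
        order = rng.permutation(len(docs))
        epoch_loss = 0.0
        for k in order:
            token_ids, token_labels = docs[k]
            for w0, w1 in windows(len(token_ids), config.window, config.window_overlap):
                optim.zero_grad()
                logits = model.forward_logits(token_ids[w0:w1])
                gold = {n: s[w0:w1] for n, s in token_labels.items()}
                loss = tagging_loss(logits, gold, weights)
                loss.backward()
                optim.step()
                epoch_loss += loss.item()
        history.append(epoch_loss / len(docs))
    return model, history


def predict(
    model: TaggingModel, text: str, doc_id: str = "pred"
) -> AnnotatedDocument:
    """Tag plain text: segment, tokenize, window, aggregate, decode."""
    words = segment_words(text)
    doc = AnnotatedDocument(doc_id=doc_id, text=text)
    if not words:
        return doc
    enc = encode_bio(doc, model.tokenizer, model.schema)
    token_ids = np.asarray(enc.flat_token_ids)
    n = len(token_ids)
    # first-window-wins label assembly over overlapping encoder windows
    token_label_ids: dict[str, np.ndarray] = {
        name: np.full(n, -1, dtype=np.intp) for name in model.heads
    }
    for w0, w1 in windows(n, model.encoder.max_len, 64):
        probs = model.forward(token_ids[w0:w1])
        for name, p in probs.items():
            pred = p.argmax(axis=-1)
            unfilled = token_label_ids[name][w0:w1] == -1
            token_label_ids[name][w0:w1][unfilled] = pred[unfilled]
    word_labels = {
        name: aggregate_tokens_to_words(seq, enc)
        for name, seq in token_label_ids.items()
    }
    if CATEGORY_SPACE not in word_labels:
        # category-head ablation: derive segmentation from assertion heads
        word_labels[CATEGORY_SPACE] = _category_from_assertions(
            word_labels, enc, model
        )
    mentions = decode_bio(
        word_labels, enc.words, model.schema, text=text, id_prefix=f"{doc_id}-m"
    )
    doc.mentions = mentions
    return doc


def _category_from_assertions(word_labels, enc, model) -> list[int]:
    cat_space = model.spaces[CATEGORY_SPACE]
    out = [cat_space.O] * enc.n_words
    for cat in model.schema.categories:
        space = model.spaces[cat]
        for i, idx in enumerate(word_labels[cat]):
            if not space.is_o(idx):
                out[i] = (
                    cat_space.b(cat) if space.is_begin(idx) else cat_space.i(cat)
                )
    return out
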