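"""Pairwise link prediction between tagged entities.

For each ordered token pair (i, j), i <= j, the concatenated pair of
encoder embeddings [e_i ; e_j] feeds two linear softmax heads: the
*link* head decides whether the two tokens belong to two mentions that
describe the same experiment, and the auxiliary *same-tag* head decides
whether they belong to one mention. The same-tag signal is redundant
given BIO tags, so it is trained (it helps fine-tune the shared
encoder) but never used at inference and never reported.

Entity-level decisions use first-token pairs, consistent with the
tagger's first-token aggregation; mean pooling over all cross-mention
token pairs is available via ``aggregation="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .documents import AnnotatedDocument
from .encoding import EncodedDocument, build_link_matrix, encode_bio
from .encoders import EncoderContract, TinyTransformerEncoder
from .nn import Adam, Linear, Tensor, concat
from .schema import DEFAULT_SCHEMA, Schema
from .segment import segment_words
from .subword import SubwordTokenizer, TrainedVocabTokenizer

__all__ = [
    "LinkTrainConfig",
    "PairBatch",
    "LinkingModel",
    "enumerate_pairs",
    "link_forward",
    "linking_loss",
    "train_linker",
    "predict_links",
]


@dataclass
class LinkTrainConfig:
    epochs: int = 14
    learning_rate: float = 1e-3
    seed: int = 0
    encoder_dim: int = 64
    encoder_layers: int = 2
    encoder_heads: int = 2
    encoder_ff: int = 128
    window: int = 512
    loss_weight_exponent: float = 0.5
    aux_lambda: float = 1.0  # weight of the same-tag auxiliary loss; 0 = off
    pair_mode: str = "tagged-only"  # training pair enumeration: "all" | "tagged-only"
    negative_cap: float = 5.0  # training negatives per positive; eval never caps
    min_word_count: int = 2
    include_within_mention: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairBatch:
    """Token-index pairs with gold link and same-tag bits."""

    i: np.ndarray  # int, i <= j elementwise
    j: np.ndarray
    link: np.ndarray  # 0/1
    sametag: np.ndarray  # 0/1

    def __len__(self) -> int:
        return len(self.i)


def _token_mention_map(enc: EncodedDocument) -> dict[int, str]:
    owner: dict[int, str] = {}
    for mid in enc.mention_word_spans:
        t0, t1 = enc.mention_token_span(mid)
        for t in range(t0, t1):
            owner[t] = mid
    return owner


def enumerate_pairs(
    enc: EncodedDocument,
    link_matrix: np.ndarray,
    mode: str = "all",
    negative_cap: float | None = None,
    rng: np.random.Generator | None = None,
) -> PairBatch:
    """Enumerate ordered token pairs (i <= j) with gold bits.

    ``mode="all"`` yields every pair; ``mode="tagged-only"`` restricts
    both indices to tokens inside gold mentions (the evaluation regime).
    ``negative_cap`` subsamples link-negative pairs to ``cap x positives``
    — training only; evaluation must pass ``None`` (exhaustive).
    """
    n = enc.n_tokens
    if mode == "all":
        idx = np.arange(n)
    elif mode == "tagged-only":
        owner = _token_mention_map(enc)
        idx = np.asarray(sorted(owner), dtype=np.intp)
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    keep = ii <= jj
    i, j = ii[keep], jj[keep]
    link = link_matrix[i, j].astype(np.int8)
    owner = _token_mention_map(enc)
    same = np.fromiter(
        (
            1 if (a in owner and owner.get(a) == owner.get(b)) else 0
            for a, b in zip(i, j)
        ),
        dtype=np.int8,
        count=len(i),
    )
    if negative_cap is not None:
        pos = np.flatnonzero(link == 1)
        neg = np.flatnonzero(link == 0)
        max_neg = int(np.ceil(negative_cap * max(len(pos), 1)))
        if len(neg) > max_neg:
            if rng is None:
                rng = np.random.default_rng(0)
            neg = rng.choice(neg, size=max_neg, replace=False)
        sel = np.sort(np.concatenate([pos, neg]))
        i, j, link, same = i[sel], j[sel], link[sel], same[sel]
    return PairBatch(i=i, j=j, link=link, sametag=same)


class LinkingModel:
    """Shared encoder + link head + auxiliary same-tag head on [e_i ; e_j]."""

    def __init__(
        self,
        encoder: EncoderContract,
        tokenizer: SubwordTokenizer,
        schema: Schema = DEFAULT_SCHEMA,
        seed: int = 0,
    ):
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.schema = schema
        rng = np.random.default_rng(seed + 2)
        self.link_head = Linear(2 * encoder.dim, 2, rng)
        self.sametag_head = Linear(2 * encoder.dim, 2, rng)

    def parameters(self) -> list[Tensor]:
        return (
            list(self.encoder.parameters())
            + self.link_head.parameters()
            + self.sametag_head.parameters()
        )


def link_forward(
    model: LinkingModel, embeddings: Tensor, pairs: PairBatch
) -> tuple[Tensor, Tensor]:
    """Per-pair (link, same-tag) 2-class logits from concatenated embeddings."""
    if embeddings.shape[-1] != model.encoder.dim:
        raise ValueError(
            f"embedding width {embeddings.shape[-1]} != encoder dim "
            f"{model.encoder.dim}"
        )
    pair_feats = concat(
        [embeddings.take_rows(pairs.i), embeddings.take_rows(pairs.j)], axis=-1
    )
    return model.link_head(pair_feats), model.sametag_head(pair_feats)


def _binary_ce(logits: Tensor, bits: np.ndarray, pos_weight: float) -> Tensor:
    y = np.asarray(bits, dtype=np.intp)
    n = len(y)
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), y] = 1.0
    nll = -(logp * Tensor(onehot)).sum(axis=-1)
    w = np.where(y == 1, pos_weight, 1.0)
    return (nll * Tensor(w)).sum() * (1.0 / n)


def linking_loss(
    link_logits: Tensor,
    sametag_logits: Tensor,
    pairs: PairBatch,
    pos_weight: float = 1.0,
    aux_lambda: float = 1.0,
) -> Tensor:
    """Weighted binary cross-entropy: link head + lambda * same-tag head."""
    loss = _binary_ce(link_logits, pairs.link, pos_weight)
    if aux_lambda != 0.0:
        loss = loss + _binary_ce(sametag_logits, pairs.sametag, pos_weight) * aux_lambda
    return loss


def train_linker(
    corpus: list[AnnotatedDocument],
    config: LinkTrainConfig = LinkTrainConfig(),
    tokenizer: SubwordTokenizer | None = None,
    schema: Schema = DEFAULT_SCHEMA,
) -> tuple[LinkingModel, list[float]]:
    """Train the linker on gold tags and links (the evaluation regime trains
    and tests the linker on ground-truth tags so tag errors do not leak in).
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
    model = LinkingModel(encoder, tokenizer, schema, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    prepared = []
    n_pos = n_neg = 0
    for doc in corpus:
        enc = encode_bio(doc, tokenizer, schema)
        if enc.n_tokens == 0 or enc.n_tokens > config.window:
            continue
        mat = build_link_matrix(doc, enc, config.include_within_mention)
        pairs = enumerate_pairs(
            enc, mat, mode=config.pair_mode,
            negative_cap=config.negative_cap, rng=rng,
        )
        if len(pairs) == 0:
            continue
        prepared.append((np.asarray(enc.flat_token_ids), pairs))
        n_pos += int(pairs.link.sum())
        n_neg += int(len(pairs) - pairs.link.sum())
    if not prepared:
        raise ValueError("no usable documents for linker training")
    pos_weight = (max(n_neg, 1) / max(n_pos, 1)) ** config.loss_weight_exponent

    optim = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(prepared))
        epoch_loss = 0.0
        for k in order:
            token_ids, pairs = prepared[k]
            optim.zero_grad()
            emb = model.encoder.embed(token_ids)
            link_logits, same_logits = link_forward(model, emb, pairs)
            loss = linking_loss(
                link_logits, same_logits, pairs,
                pos_weight=pos_weight, aux_lambda=config.aux_lambda,
            )
            loss.backward()
            optim.step()
            epoch_loss += loss.item()
        history.append(epoch_loss / len(prepared))
    return model, history


def predict_links(
    model: LinkingModel,
    doc: AnnotatedDocument,
    threshold: float = 0.5,
    aggregation: str = "first",
) -> set[frozenset[str]]:
    """Predict the set of linked (unordered) mention-id pairs in one document.

    Uses the document's mentions (gold or predicted by the tagger). The
    decision for a mention pair reads the link probability of their
    first-token pair (``aggregation="first"``) or the mean over all
    cross-mention token pairs (``aggregation="mean"``).
    """
    enc = encode_bio(doc, model.tokenizer, model.schema)
    mids = [m.id for m in doc.mentions if m.id in enc.mention_word_spans]
    if len(mids) < 2:
        return set()
    token_ids = np.asarray(enc.flat_token_ids)
    emb = model.encoder.embed(token_ids)

    if aggregation == "first":
        firsts = {mid: enc.mention_token_span(mid)[0] for mid in mids}
        pair_list = []
        index_pairs = []
        for a in range(len(mids)):
            for b in range(a + 1, len(mids)):
                i, j = firsts[mids[a]], firsts[mids[b]]
                if i > j:
                    i, j = j, i
                pair_list.append((mids[a], mids[b]))
                index_pairs.append((i, j))
        batch = PairBatch(
            i=np.asarray([p[0] for p in index_pairs]),
            j=np.asarray([p[1] for p in index_pairs]),
            link=np.zeros(len(index_pairs), dtype=np.int8),
            sametag=np.zeros(len(index_pairs), dtype=np.int8),
        )
        link_logits, _ = link_forward(model, emb, batch)
        probs = link_logits.softmax(axis=-1).data[:, 1]
        return {
            frozenset(pair)
            for pair, p in zip(pair_list, probs)
            if p >= threshold
        }
    elif aggregation == "mean":
        out: set[frozenset[str]] = set()
        spans = {mid: enc.mention_token_span(mid) for mid in mids}
        for a in range(len(mids)):
            for b in range(a + 1, len(mids)):
                (a0, a1), (b0, b1) = spans[mids[a]], spans[mids[b]]
                ii, jj = np.meshgrid(
                    np.arange(a0, a1), np.arange(b0, b1), indexing="ij"
                )
                i, j = np.minimum(ii, jj).ravel(), np.maximum(ii, jj).ravel()
                batch = PairBatch(
                    i=i, j=j,
                    link=np.zeros(len(i), dtype=np.int8),
                    sametag=np.zeros(len(i), dtype=np.int8),
                )
                link_logits, _ = link_forward(model, emb, batch)
                if link_logits.softmax(axis=-1).data[:, 1].mean() >= threshold:
                    out.add(frozenset((mids[a], mids[b])))
        return out
    raise ValueError(f"unknown aggregation {aggregation!r}")
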