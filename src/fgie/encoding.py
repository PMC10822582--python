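"""BIO codec: document annotations <-> model-facing encodings.

A document is encoded as words, sub-word tokens, and **five** word-level
BIO label sequences: one *category* space over ``{B,I} x 4 categories
U {O}`` and, per category, an *assertion* space over ``{B,I} x assertions
U {O}``. Links are encoded as an upper-triangular binary matrix over
tokens: entry ``(i, j)``, ``i <= j``, is 1 iff tokens *i* and *j* belong
to two distinct mentions that co-occur in at least one link group.
Token pairs inside a single mention default to 0 — the span structure is
already carried by the BIO labels and the auxiliary same-tag objective —
but the opposite convention is available via ``include_within_mention``.

Decoding accepts arbitrary (possibly inconsistent) model output: maximal
``B I*`` runs in the category space become mentions, an orphan ``I`` is
treated as ``B``, and the assertion is the majority vote over the run in
the matching assertion space (ties broken by run order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .documents import AnnotatedDocument, EntityMention
from .schema import DEFAULT_SCHEMA, Schema
from .segment import Word, segment_words, snap_span_to_words
from .subword import SubwordTokenizer

__all__ = [
    "LabelSpace",
    "label_spaces",
    "CATEGORY_SPACE",
    "EncodedDocument",
    "encode_bio",
    "decode_bio",
    "build_link_matrix",
    "aggregate_tokens_to_words",
    "expand_word_labels_to_tokens",
]

CATEGORY_SPACE = "category"


class LabelSpace:
    """A BIO label inventory: index 0 is ``O``; ``B-t``/``I-t`` per tag ``t``."""

    O = 0

    def __init__(self, name: str, tags: Sequence[str]):
        self.name = name
        self.tags = tuple(tags)
        self.labels: tuple[str, ...] = ("O",) + tuple(
            f"{bi}-{t}" for t in tags for bi in ("B", "I")
        )
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def size(self) -> int:
        return len(self.labels)

    def b(self, tag: str) -> int:
        return self._index[f"B-{tag}"]

    def i(self, tag: str) -> int:
        return self._index[f"I-{tag}"]

    def is_o(self, idx: int) -> bool:
        return idx == self.O

    def is_begin(self, idx: int) -> bool:
        return idx != self.O and (idx - 1) % 2 == 0

    def tag_of(self, idx: int) -> str | None:
        return None if idx == self.O else self.tags[(idx - 1) // 2]


def label_spaces(schema: Schema = DEFAULT_SCHEMA) -> dict[str, LabelSpace]:
    """The five label spaces: the category space plus one per category."""
    spaces = {CATEGORY_SPACE: LabelSpace(CATEGORY_SPACE, schema.categories)}
    for cat in schema.categories:
        spaces[cat] = LabelSpace(cat, schema.assertions[cat])
    return spaces


@dataclass
class EncodedDocument:
    """Words, sub-word tokens, five word-level BIO sequences, link matrix inputs."""

    doc_id: str
    words: list[Word]
    token_ids: list[list[int]]  # per word
    labels: dict[str, list[int]]  # space name -> word-level label ids
    mention_word_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_tokens(self) -> int:
        return sum(len(t) for t in self.token_ids)

    @property
    def flat_token_ids(self) -> list[int]:
        return [t for toks in self.token_ids for t in toks]

    @property
    def token_word_index(self) -> list[int]:
        """For each token, the index of the word it belongs to."""
        out: list[int] = []
        for w, toks in enumerate(self.token_ids):
            out.extend([w] * len(toks))
        return out

    @property
    def word_first_token(self) -> list[int]:
        """For each word, the flat index of its first token."""
        out: list[int] = []
        pos = 0
        for toks in self.token_ids:
            out.append(pos)
            pos += len(toks)
        return out

    def mention_token_span(self, mention_id: str) -> tuple[int, int]:
        w0, w1 = self.mention_word_spans[mention_id]
        first = self.word_first_token
        start = first[w0]
        end = first[w1] if w1 < self.n_words else self.n_tokens
        return start, end


def encode_bio(
    doc: AnnotatedDocument,
    tokenizer: SubwordTokenizer,
    schema: Schema = DEFAULT_SCHEMA,
) -> EncodedDocument:
    """Encode a document into words, tokens and the five BIO label sequences.

    Mention boundaries that fall mid-word are snapped outward (with a
    logged warning). The first word of each mention takes the ``B`` label,
    subsequent words ``I``, in both the category space and that category's
    assertion space; the other three assertion spaces stay ``O`` there.
    """
    words = segment_words(doc.text)
    spaces = label_spaces(schema)
    labels = {name: [LabelSpace.O] * len(words) for name in spaces}
    token_ids = [tokenizer.tokenize(w.surface) for w in words]
    mention_word_spans: dict[str, tuple[int, int]] = {}

    starts = {w.start: i for i, w in enumerate(words)}
    ends = {w.end: i for i, w in enumerate(words)}

    for m in doc.mentions:
        s, e = snap_span_to_words(m.start, m.end, words, context=f"mention {m.id}")
        if s not in starts or e not in ends:
            covered = [i for i, w in enumerate(words) if w.start >= s and w.end <= e]
            if not covered:
                continue
            w0, w1 = covered[0], covered[-1] + 1
        else:
            w0, w1 = starts[s], ends[e] + 1
        mention_word_spans[m.id] = (w0, w1)
        cat_space = spaces[CATEGORY_SPACE]
        ass_space = spaces[m.category]
        for k, w in enumerate(range(w0, w1)):
            if k == 0:
                labels[CATEGORY_SPACE][w] = cat_space.b(m.category)
                labels[m.category][w] = ass_space.b(m.assertion)
            else:
                labels[CATEGORY_SPACE][w] = cat_space.i(m.category)
                labels[m.category][w] = ass_space.i(m.assertion)

    return EncodedDocument(
        doc_id=doc.doc_id,
        words=words,
        token_ids=token_ids,
        labels=labels,
        mention_word_spans=mention_word_spans,
    )


def decode_bio(
    word_labels: dict[str, Sequence[int]],
    words: list[Word],
    schema: Schema = DEFAULT_SCHEMA,
    text: str | None = None,
    id_prefix: str = "m",
) -> list[EntityMention]:
    """Decode five word-level label sequences into entity mentions."""
    spaces = label_spaces(schema)
    cat_space = spaces[CATEGORY_SPACE]
    cat_seq = word_labels[CATEGORY_SPACE]
    mentions: list[EntityMention] = []
    n = len(words)
    i = 0
    while i < n:
        idx = cat_seq[i]
        if cat_space.is_o(idx):
            i += 1
            continue
        category = cat_space.tag_of(idx)
        j = i + 1
        # extend over I-labels of the same category (orphan I already
        # handled: any non-O label opens a run)
        while (
            j < n
            and not cat_space.is_o(cat_seq[j])
            and not cat_space.is_begin(cat_seq[j])
            and cat_space.tag_of(cat_seq[j]) == category
        ):
            j += 1
        assertion = _majority_assertion(
            word_labels[category][i:j], spaces[category], schema, category
        )
        start, end = words[i].start, words[j - 1].end
        surface = (
            text[start:end]
            if text is not None
            else " ".join(w.surface for w in words[i:j])
        )
        mentions.append(
            EntityMention(
                id=f"{id_prefix}{len(mentions)}",
                category=category,
                assertion=assertion,
                start=start,
                end=end,
                surface=surface,
            )
        )
        i = j
    return mentions


def _majority_assertion(
    run_labels: Sequence[int], space: LabelSpace, schema: Schema, category: str
) -> str:
    counts: dict[str, int] = {}
    order: list[str] = []
    for idx in run_labels:
        tag = space.tag_of(idx)
        if tag is None:
            continue
        if tag not in counts:
            counts[tag] = 0
            order.append(tag)
        counts[tag] += 1
    if not counts:
        return schema.assertions[category][0]  # no in-category evidence
    best = max(counts.values())
    return next(t for t in order if counts[t] == best)


def build_link_matrix(
    doc: AnnotatedDocument,
    enc: EncodedDocument,
    include_within_mention: bool = False,
) -> np.ndarray:
    """Upper-triangular 0/1 matrix over tokens encoding pairwise links."""
    n = enc.n_tokens
    mat = np.zeros((n, n), dtype=np.int8)
    spans = {
        mid: enc.mention_token_span(mid)
        for mid in enc.mention_word_spans
    }
    for pair in doc.linked_pairs():
        a, b = tuple(pair)
        if a not in spans or b not in spans:
            continue
        (a0, a1), (b0, b1) = spans[a], spans[b]
        for i in range(a0, a1):
            for j in range(b0, b1):
                lo, hi = (i, j) if i <= j else (j, i)
                mat[lo, hi] = 1
    if include_within_mention:
        for m0, m1 in spans.values():
            for i in range(m0, m1):
                for j in range(i, m1):
                    mat[i, j] = 1
    return mat


def aggregate_tokens_to_words(
    token_sequence: Sequence, enc: EncodedDocument
) -> list:
    """First-token aggregation: each word's prediction is its first token's."""
    first = enc.word_first_token
    return [token_sequence[t] for t in first]


def expand_word_labels_to_tokens(
    enc: EncodedDocument,
) -> dict[str, list[int]]:
    """Copy each word's labels onto every one of its sub-word tokens."""
    twi = enc.token_word_index
    return {
        name: [seq[w] for w in twi] for name, seq in enc.labels.items()
    }
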