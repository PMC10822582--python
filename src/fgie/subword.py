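"""Sub-word tokenization behind a pluggable contract.

The models consume sub-word token ids; any tokenizer satisfying
:class:`SubwordTokenizer` can be plugged in (a pretrained biomedical
encoder's WordPiece vocabulary at full scale). The bundled default is a
small vocabulary trained on the working corpus: frequent words are single
pieces, rare words fall back to greedy longest-match over character
pieces with ``##`` continuation marking, so multi-token words (and hence
first-token aggregation) genuinely occur.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Protocol

__all__ = ["SubwordTokenizer", "TrainedVocabTokenizer"]

UNK = "[UNK]"
PAD = "[PAD]"


class SubwordTokenizer(Protocol):
    """Contract: map one word to a non-empty list of token ids."""

    vocab_size: int

    def tokenize(self, word: str) -> list[int]: ...


class TrainedVocabTokenizer:
    """Greedy longest-match tokenizer over a corpus-trained piece vocabulary."""

    def __init__(self, pieces: Iterable[str]):
        vocab = [PAD, UNK] + sorted(set(pieces))
        self.piece_to_id = {p: i for i, p in enumerate(vocab)}
        self.id_to_piece = vocab
        self.vocab_size = len(vocab)
        self.unk_id = self.piece_to_id[UNK]
        self._max_piece = max((len(p) for p in vocab), default=1)

    @classmethod
    def train(
        cls, words: Iterable[str], min_word_count: int = 2, lowercase: bool = False
    ) -> "TrainedVocabTokenizer":
        counts = Counter(w.lower() if lowercase else w for w in words)
        pieces: set[str] = set()
        for word, c in counts.items():
            if c >= min_word_count:
                pieces.add(word)
            for i, ch in enumerate(word):  # char fallback, with continuations
                pieces.add(ch if i == 0 else "##" + ch)
        return cls(pieces)

    def tokenize(self, word: str) -> list[int]:
        if word in self.piece_to_id:
            return [self.piece_to_id[word]]
        ids: list[int] = []
        pos = 0
        while pos < len(word):
            prefix = "" if pos == 0 else "##"
            match_id = None
            for length in range(min(self._max_piece, len(word) - pos), 0, -1):
                piece = prefix + word[pos : pos + length]
                if piece in self.piece_to_id:
                    match_id = self.piece_to_id[piece]
                    pos += length
                    break
            if match_id is None:
                match_id = self.unk_id
                pos += 1
            ids.append(match_id)
        return ids or [self.unk_id]

    def to_dict(self) -> dict:
        return {"pieces": self.id_to_piece[2:]}

    @classmethod
    def from_dict(cls, obj: dict) -> "TrainedVocabTokenizer":
        return cls(obj["pieces"])
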