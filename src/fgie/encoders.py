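"""Token encoders behind a pluggable contract.

The tagging and linking heads consume per-token embeddings from any
object satisfying :class:`EncoderContract`. The bundled desk-scale
default is :class:`TinyTransformerEncoder`, a small self-attention
encoder trained from scratch; at full scale a pretrained biomedical
encoder (e.g. a BERT-family model fine-tuned on PubMed text) slots in
behind the same contract — see ``configs/full_scale.json``.
:class:`FrozenRandomEncoder` is a fixed, context-free embedding table
used by linear-probe sanity tests.
"""

from __future__ import annotations

import math
from typing import Protocol

import numpy as np

from .nn import Embedding, LayerNorm, Linear, Tensor, concat

__all__ = [
    "EncoderContract",
    "TinyTransformerEncoder",
    "FrozenRandomEncoder",
    "windows",
]


class EncoderContract(Protocol):
    """Map a token-id sequence to one d-dimensional vector per token."""

    dim: int
    max_len: int

    def embed(self, token_ids: np.ndarray) -> Tensor: ...

    def parameters(self) -> list[Tensor]: ...


class _SelfAttention:
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        assert d % n_heads == 0
        self.d, self.h, self.dh = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        q = self.wq(x).reshape(n, self.h, self.dh).transpose(1, 0, 2)
        k = self.wk(x).reshape(n, self.h, self.dh).transpose(1, 0, 2)
        v = self.wv(x).reshape(n, self.h, self.dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(n, self.d)
        return self.wo(out)

    def parameters(self) -> list[Tensor]:
        return (
            self.wq.parameters() + self.wk.parameters()
            + self.wv.parameters() + self.wo.parameters()
        )


class _Block:
    """Pre-norm transformer block: attention + position-wise feed-forward."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = _SelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, d_ff, rng)
        self.ff2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())

    def parameters(self) -> list[Tensor]:
        return (
            self.ln1.parameters() + self.attn.parameters()
            + self.ln2.parameters() + self.ff1.parameters()
            + self.ff2.parameters()
        )


class TinyTransformerEncoder:
    """Small trainable self-attention encoder (desk-scale default)."""

    def __init__(
        self,
        vocab_size: int,
        dim: int = 64,
        n_layers: int = 2,
        n_heads: int = 2,
        d_ff: int = 128,
        max_len: int = 512,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.max_len = max_len
        self.vocab_size = vocab_size
        self.tok = Embedding(vocab_size, dim, rng)
        self.pos = Embedding(max_len, dim, rng)
        self.blocks = [_Block(dim, n_heads, d_ff, rng) for _ in range(n_layers)]
        self.ln_out = LayerNorm(dim)

    def embed(self, token_ids: np.ndarray) -> Tensor:
        token_ids = np.asarray(token_ids, dtype=np.intp)
        n = len(token_ids)
        if n > self.max_len:
            raise ValueError(f"sequence of {n} tokens exceeds window {self.max_len}")
        x = self.tok(token_ids) + self.pos(np.arange(n))
        for block in self.blocks:
            x = block(x)
        return self.ln_out(x)

    def parameters(self) -> list[Tensor]:
        params = self.tok.parameters() + self.pos.parameters()
        for b in self.blocks:
            params += b.parameters()
        return params + self.ln_out.parameters()


class FrozenRandomEncoder:
    """Deterministic, context-free random embeddings; never trained."""

    def __init__(self, vocab_size: int, dim: int = 32, seed: int = 0,
                 max_len: int = 100000):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.max_len = max_len
        self.table = rng.normal(0.0, 1.0, (vocab_size, dim))

    def embed(self, token_ids: np.ndarray) -> Tensor:
        return Tensor(self.table[np.asarray(token_ids, dtype=np.intp)])

    def parameters(self) -> list[Tensor]:
        return []


def windows(n: int, size: int, overlap: int) -> list[tuple[int, int]]:
    """Cover ``range(n)`` with windows of ``size`` overlapping by ``overlap``.

    Label conflicts in the overlap are resolved first-window-wins by the
    caller (the first window's predictions are kept for positions it covers).
    """
    if n <= size:
        return [(0, n)]
    step = size - overlap
    out = []
    start = 0
    while start < n:
        end = min(start + size, n)
        out.append((start, end))
        if end == n:
            break
        start += step
    return out
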