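"""Model directory persistence.

A model directory holds ``config.json`` (training configuration +
model kind + schema fingerprint), ``tokenizer.json`` (the trained piece
vocabulary) and ``weights.npz`` (parameter arrays in construction
order). Parameter enumeration order is deterministic given the
configuration, so loading reconstructs the network and copies arrays in.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .encoders import TinyTransformerEncoder
from .linking import LinkingModel, LinkTrainConfig
from .schema import DEFAULT_SCHEMA, Schema
from .subword import TrainedVocabTokenizer
from .tagging import TaggingModel, TrainConfig

__all__ = ["save_tagger", "load_tagger", "save_linker", "load_linker"]


def schema_fingerprint(schema: Schema) -> str:
    payload = json.dumps(
        {c: list(schema.assertions[c]) for c in schema.categories},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _save(path: Path, kind: str, config_dict: dict, tokenizer, params) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": kind,
        "config": config_dict,
        "schema_fingerprint": schema_fingerprint(DEFAULT_SCHEMA),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    (path / "tokenizer.json").write_text(json.dumps(tokenizer.to_dict()))
    np.savez(path / "weights.npz",
             **{f"p{i}": p.data for i, p in enumerate(params)})


def _load_meta(path: Path, expect_kind: str) -> tuple[dict, TrainedVocabTokenizer]:
    meta = json.loads((path / "config.json").read_text())
    if meta["kind"] != expect_kind:
        raise ValueError(f"{path} holds a {meta['kind']} model, not {expect_kind}")
    if meta["schema_fingerprint"] != schema_fingerprint(DEFAULT_SCHEMA):
        raise ValueError(f"{path}: schema fingerprint mismatch")
    tokenizer = TrainedVocabTokenizer.from_dict(
        json.loads((path / "tokenizer.json").read_text())
    )
    return meta, tokenizer


def _restore_weights(path: Path, params) -> None:
    arrays = np.load(path / "weights.npz")
    if len(arrays.files) != len(params):
        raise ValueError(
            f"{path}: {len(arrays.files)} stored arrays for "
            f"{len(params)} parameters"
        )
    for i, p in enumerate(params):
        p.data = arrays[f"p{i}"]


def save_tagger(model: TaggingModel, config: TrainConfig, path: str | Path) -> None:
    _save(Path(path), "tagger", config.to_dict(), model.tokenizer,
          model.parameters())


def load_tagger(path: str | Path) -> TaggingModel:
    path = Path(path)
    meta, tokenizer = _load_meta(path, "tagger")
    config = TrainConfig(**meta["config"])
    encoder = TinyTransformerEncoder(
        vocab_size=tokenizer.vocab_size, dim=config.encoder_dim,
        n_layers=config.encoder_layers, n_heads=config.encoder_heads,
        d_ff=config.encoder_ff, max_len=config.window, seed=config.seed,
    )
    model = TaggingModel(
        encoder, tokenizer, seed=config.seed,
        include_category_head=config.include_category_head,
    )
    _restore_weights(path, model.parameters())
    return model


def save_linker(model: LinkingModel, config: LinkTrainConfig,
                path: str | Path) -> None:
    _save(Path(path), "linker", config.to_dict(), model.tokenizer,
          model.parameters())


def load_linker(path: str | Path) -> LinkingModel:
    path = Path(path)
    meta, tokenizer = _load_meta(path, "linker")
    config = LinkTrainConfig(**meta["config"])
    encoder = TinyTransformerEncoder(
        vocab_size=tokenizer.vocab_size, dim=config.encoder_dim,
        n_layers=config.encoder_layers, n_heads=config.encoder_heads,
        d_ff=config.encoder_ff, max_len=config.window, seed=config.seed,
    )
    model = LinkingModel(encoder, tokenizer, seed=config.seed)
    _restore_weights(path, model.parameters())
    return model
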