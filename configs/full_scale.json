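{
  "description": "Full-scale configuration: fine-tune a pretrained biomedical encoder on the released 800-abstract corpus. Requires a transformer runtime and the pretrained weights; the desk-scale numpy encoder bundled with this package is not used in this configuration.",
  "corpus": {
    "source": "local checkout of the released annotated corpus (see README)",
    "path": "data/released",
    "n_docs": 800
  },
  "encoder": {
    "kind": "pretrained-biomedical-bert",
    "model_name": "dmis-lab/biobert-base-cased-v1.1",
    "hidden_size": 768,
    "max_len": 512,
    "fine_tune": true
  },
  "tagger": {
    "heads": ["category", "PerturbingAction", "Context", "Effect", "Phenotype"],
    "shared_encoder": true,
    "loss": "class-weighted cross-entropy",
    "loss_weight_exponent": 1.0,
    "learning_rate": 3e-5,
    "epochs": 10
  },
  "linker": {
    "pair_features": "concatenated token-embedding pairs [e_i ; e_j], i <= j",
    "heads": ["link", "same-tag (auxiliary, train-only)"],
    "loss": "balanced binary cross-entropy",
    "aux_lambda": 1.0,
    "train_on_gold_tags": true,
    "learning_rate": 3e-5,
    "epochs": 10
  },
  "evaluation": {
    "holdout_fraction": 0.10,
    "k_folds": 4,
    "tagging_level": "word (first-token aggregation)",
    "linking_candidates": "all pairs of tagged tokens, exhaustive"
  }
}
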