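# fgie — functional-genomics information extraction

Cancer-genomics papers report what happens when a gene is perturbed in
a particular experimental setting — but that information is locked in
prose. `fgie` extracts it: given abstract text, it tags four categories
of experiment-describing entities and predicts which of them belong to
the same experiment.

- **Perturbing action** — a manipulation of a named gene
  (`"Silencing Lnc-EPIC1 by siRNA"`), with an assertion from
  {gene loss-of-function, gene gain-of-function, RNAi/knockdown,
  pharmacological inhibition, pharmacological augmentation, other};
- **Context** — the experimental model (`"PC cells"`), 11 assertions
  from *patient* to *in vivo*;
- **Effect** — the direction of regulation (`"inhibit"`), 5 assertions;
- **Phenotype** — the induced behaviour change (`"apoptosis"`), a
  closed vocabulary of 31 cell-death/cancer/cell-biology terms;
- **Link group** — four entities, one per category, describing one
  experiment; entities are shared across the groups of an experiment.

The package is aimed at text-mining and biomedical-NLP researchers who
want a complete, inspectable reference pipeline for this task: corpus
IO and validation, the BIO encoding with five label spaces, the
two neural models, the full evaluation protocol with its co-occurrence
baseline, a synthetic gold-annotated corpus generator so everything
runs offline at desk scale, and the gene-level case-study aggregation.

## Models in brief

A shared token encoder feeds linear softmax heads. The **tagger** has
five heads — a category head over BIO-encoded categories and four
assertion heads, one per category — trained jointly with class-weighted
cross-entropy, `weight(c) ∝ (total/count(c))^q`, normalised to mean 1
(the O class is weighted too). Token predictions become word
predictions by the first-token rule, and words decode back to mentions
via maximal `B I*` runs with majority-vote assertions. The **linker**
scores every ordered token pair (i ≤ j) from the concatenated
embeddings `[e_i ; e_j]` with a link head and an auxiliary same-tag
head (train-only); an entity pair is linked when its first-token pair's
probability reaches 0.5. Tagging P/R/F1 counts a non-O/non-O label swap
as both a false positive and a false negative; linking P/R/F1 is set
arithmetic over the exhaustive candidate pairs of tagged mentions.

The desk-scale encoder is a small from-scratch transformer implemented
in numpy (no deep-learning framework required); the full-scale
configuration in `configs/full_scale.json` declares the same
architecture over a pretrained biomedical BERT encoder and the released
800-abstract corpus — that run needs a transformer runtime and GPU-scale
compute. See `docs/methods.md` for the complete model and protocol
description and `docs/formats.md` for the file formats.

## Worked example

```python
from fgie import (lnc_epic1_example, cooccurrence_baseline,
                  entity_pair_candidates, linking_prf)

doc = lnc_epic1_example()   # 1 sentence, 9 mentions, 4 link groups
pred = cooccurrence_baseline(doc)
r = linking_prf(pred, doc.linked_pairs(), entity_pair_candidates(doc))
print(len(pred), len(doc.linked_pairs()))
print(f"{r.precision:.3f} {r.recall:.3f} {r.f1:.3f}")
```

prints

```
36 18
0.500 1.000 0.667
```

the nine entities share one sentence, so the baseline predicts all
C(9,2) = 36 pairs; only 18 pairs actually co-occur in a link group, so
precision is 0.5 at perfect recall. The `examples/` directory has one
short script per capability (worked example, corpus generation, tagger
training, linker vs baseline, case-study aggregation), each printing
the numbers it computes and what they mean.

## Command line

```bash
fgie synth --n-docs 100 --seed 1 --out corpus.jsonl
fgie stats corpus.jsonl
fgie train-tagger --corpus corpus.jsonl --out tagger/
fgie predict --model tagger/ --in abstract.txt --out pred.json
fgie train-linker --corpus corpus.jsonl --out linker/
fgie link --linker linker/ --in corpus.jsonl --out links.json
fgie baseline --corpus corpus.jsonl
fgie casestudy --pred corpus.jsonl --links links.json --genes genes.tsv \
     --phenotype apoptosis --grouping invitro_invivo
```

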