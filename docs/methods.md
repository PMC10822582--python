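# Methods

## Task and annotation model

The package extracts structured descriptions of gene-perturbation
experiments from abstract text. Four entity categories are marked as
contiguous character spans: **perturbing action** (an experimental
manipulation of a named gene: knockout, RNAi, overexpression, drug
inhibition/augmentation — every perturbing action contains a gene name),
**context** (the experimental model: patients, organisms, tissues,
neoplasms, grafts, xenografts, cells, transformed cells, organoids,
*in vitro*, *in vivo*), **effect** (the direction of regulation:
positive, negative, regulates, rescues, no effect) and **phenotype**
(a closed vocabulary of 31 cell-death, cancer and general cell-biology
terms). Each mention carries exactly one *assertion* from its
category's vocabulary (6 / 11 / 5 / 31 terms respectively). A **link
group** is a set of four mentions, one per category, describing one
experiment; one experiment sentence often yields several groups that
share mentions (a single perturbing action can participate in every
group of its experiment), and a group's mentions can span two
sentences. Mentions may also remain unlinked. Multi-context readings
("Cells; Organism") are modelled as multiple single-assertion mentions;
the case-study aggregation renders the combined label.

## Encoding

Text is segmented into words (whitespace chunks with edge punctuation
split off; symbol runs like `-/-` survive), each word into sub-word
tokens by a pluggable tokenizer. Labels live in five word-level BIO
spaces: one *category* space over `{B,I}×4 ∪ {O}` and four per-category
*assertion* spaces over `{B,I}×assertions ∪ {O}`. Word labels are
copied onto each of the word's tokens for training; token predictions
are converted back to words by taking the first token's prediction
(averaging and max pooling behave similarly; first-token is the
simplest). Links are encoded as an upper-triangular binary matrix over
tokens: entry (i, j), i ≤ j, is 1 iff tokens i and j belong to two
distinct mentions co-occurring in at least one group. Token pairs
inside one mention are 0 by default — span structure is already carried
by the BIO labels and the same-tag objective — with the opposite
convention available behind `include_within_mention`.

Decoding accepts inconsistent model output: maximal `B I*` runs in the
category space become mentions, orphan `I` opens a run, and the
assertion is the majority vote over the run in the matching assertion
space (ties → first in the run; a run with no in-category assertion
evidence falls back to the first assertion of the category's
vocabulary, a rare degenerate case).

## Models

Both models share the same two-part shape: a token encoder and linear
softmax heads.

**Tagger.** Five heads (category + four assertion heads) read each
token embedding. The category head increases the effective supervision
for the shared encoder; assertion spaces are supervised on all words,
O class included. Loss is the sum over heads of class-weighted
cross-entropy, averaged per token within each head. Class weights are
`(total/count)^q` normalised to mean 1 per space; unseen classes get
the maximum observed weight. `q = 0` disables balancing; the package
default is `q = 0.5` (milder than full inverse frequency, which
over-predicts rare classes at desk scale), and the balancing-direction
experiment compares `q = 1` against `q = 0` explicitly.

**Linker.** For each ordered token pair (i, j), i ≤ j, the concatenated
embeddings `[e_i ; e_j]` feed a *link* head and an auxiliary *same-tag*
head (is the pair inside one mention?). The same-tag signal is
redundant given BIO tags and is never used at inference or reported,
but training it improves encoder fine-tuning. Loss is balanced binary
cross-entropy (positive weight `(neg/pos)^q`) plus λ times the same-tag
term (λ = 1 default; λ = 0 gives the ablation without the auxiliary
head). Entity pairs are decided by the link probability of the two
mentions' first-token pair at threshold 0.5 (not tuned); mean pooling
over all cross-mention token pairs is available. Training enumerates
pairs over tagged tokens by default with negatives subsampled at 5:1
per document (pair enumeration over all tokens is available via
`pair_mode="all"`; it is quadratic and, at desk scale, mismatched with
the evaluation distribution, which considers tagged tokens). Evaluation
is always exhaustive — never subsampled. The linker is trained and
evaluated on ground-truth tags so tagging errors do not contaminate the
linking measurement.

**Encoders.** The encoder is a contract (token ids → per-token
vectors), so the desk and full-scale configurations differ only in the
plug-in. The desk-scale default is a small transformer trained from
scratch — learned token and position embeddings, 2 pre-norm
self-attention blocks, width 64, 2 heads, feed-forward 128 — implemented
in numpy with a compact reverse-mode autodiff (gradient-checked against
finite differences) and optimised with Adam (lr 1e-3). The full-scale
configuration (`configs/full_scale.json`) declares a pretrained
biomedical BERT encoder fine-tuned end to end (lr 3e-5); running it
requires a transformer runtime and GPU-scale compute and is outside
desk scope. Sequences longer than the 512-token window are covered by
overlapping windows (overlap 64) with first-window-wins label
resolution; abstracts essentially always fit one window.

## Evaluation protocol

Documents are split 10% holdout + 4 cross-validation folds over the
rest (document-level, sizes within 1, seeded). Tagging is scored per
word after first-token aggregation, micro-averaged within each head
(the TP/FP/FN definitions are class-agnostic counts, so micro is the
natural reading): prediction = gold ≠ O is a TP; a wrong non-O
prediction is a FP; a wrong prediction whose gold is non-O is a FN — a
non-O/non-O swap counts as both FP and FN, and precision/recall divide
by TP+FP and TP+FN respectively. Linking is scored over the exhaustive
set of unordered pairs of distinct tagged mentions. The
**co-occurrence baseline** links every pair of mentions whose spans
share a sentence; it is evaluated on the same entity-pair candidate
space as the model so the scores are commensurable. The sentence
splitter is pluggable; the default is rule-based with abbreviation
handling, and splitter choice shifts the corpus-level baseline F1
slightly.

## Synthetic corpus

The generator emulates the real corpus's structure so every stage
trains and tests offline. One experiment = one perturbing-action phrase
plus one or two effect blocks (effect verb + 1–2 phenotypes + context);
each block contributes one link group per phenotype, so a two-block ×
two-phenotype experiment reproduces the canonical pattern of one
perturbing action in four groups. With probability `p_multisentence`
(default 0.3) the second block is realised in a following sentence,
creating cross-sentence groups that cap baseline recall below 1.
`p_distractor` (default 0.4) controls the fraction of unannotated
introduction/discussion-style sentences that deliberately contain
schema vocabulary — gene names and phenotype terms outside experiment
descriptions — which is what makes surface form alone insufficient for
tagging. `assertion_skew` (default 1.0; 2.0 in the balancing study)
draws assertions from a power law over vocabulary rank, producing the
rare classes that loss balancing targets. A block occasionally emits an
extra marked-but-unlinked phenotype (`p_unlinked_extra = 0.15`),
mirroring the real corpus where many marked entities join no group.
Gene and cell-line lexicons are small bundled invented-name lists; the
exact gene span inside every perturbing action is recorded as
bookkeeping for the case study.

What the generator does **not** emulate: real lexical diversity and
paraphrase (surfaces come from short template lists), nested or
discontinuous mentions, annotator disagreement and boundary noise,
abbreviation-heavy clinical prose. Passing the synthetic-recovery
checks therefore shows the pipeline is correct and learnable end to
end, not that the desk-scale encoder would reach the full-scale scores
on real abstracts — that configuration is shipped but requires the
pretrained encoder and the released corpus.

## Study conditions and problem sizes

- Synthetic recovery: train 500 documents, test 100, tagger 12 epochs,
  linker 14 epochs, all at default generator settings.
- Balancing direction: train 200 / test 250 documents at skew 2.0 with
  a deliberately short 4-epoch schedule — class weighting is a remedy
  for data/compute-limited training, and at convergence the templated
  task is learnable by both arms, so the comparison is run in the
  non-converged regime where the mechanism operates. Three paired run
  seeds per arm with TP/FN pooled across runs; rare = classes at or
  below the median observed non-O training frequency in the phenotype
  and context heads. Reported as a direction (pooled balanced −
  unweighted rare-class recall).
- Metric oracle equivalence: 1000 random instances per metric against
  explicit-loop recounts.
- Round trip: 500 generated documents through XML, JSON and the BIO
  codec.

## Numerical choices and degenerate inputs

F1 is 0 when TP = 0 (and precision/recall are 0 when their denominator
is 0). Mention spans that fall mid-word are snapped outward with a
logged warning. Empty text yields an empty prediction. The
equal-probability tie at the 0.5 linking threshold counts as a
predicted link (≥). Training is deterministic given the config seed on
one device; corpus generation is byte-identical under a fixed seed.

## Known limitations

- The desk-scale encoder is intentionally small; its scores on real
  prose would be limited by vocabulary coverage (the bundled tokenizer
  is corpus-trained, with character-piece fallback).
- Four-entity group reconstruction from pairwise links is deliberately
  not attempted; downstream aggregation consumes pairwise associations.
- Gene-mention recognition is consumed as external input, never
  computed.
- Inter-annotator agreement statistics are out of scope (they belong to
  the annotation tool, not this pipeline).
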