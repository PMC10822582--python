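"""Synthetic gold-annotated abstracts with the structure of the real corpus.

Each document interleaves *experiment descriptions* — template-realised
sentences whose entities are marked and grouped into four-entity links —
with *distractor* sentences: introduction/discussion-style text that
contains schema vocabulary (gene names, phenotype terms) but is **not**
annotated, mirroring the annotation rule that only experiment
descriptions are marked. The distractors are what makes tagging
nontrivial (surface form alone does not determine the label) and entity
reuse across groups is what makes the co-occurrence baseline imperfect.

One experiment is one perturbing action plus one or two effect blocks;
each block carries an effect verb, one or two phenotypes and a context,
and contributes one link group per phenotype — so a two-block, two-
phenotype experiment reproduces the canonical pattern of one perturbing
action participating in four groups. With probability ``p_multisentence``
the second block is realised in a following sentence, producing
cross-sentence link groups (the four entities of a group then span two
sentences, and baseline recall drops below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .documents import AnnotatedDocument, EntityMention, LinkGroup, validate
from .schema import (
    CONTEXT,
    DEFAULT_SCHEMA,
    EFFECT,
    PERTURBING_ACTION,
    PHENOTYPE,
    Schema,
)
from .segment import split_sentences

__all__ = ["SynthConfig", "generate_corpus", "generate_corpus_detailed",
           "corpus_summary"]

GENES = [
    "TP53", "KRAS", "MYC", "BRCA1", "EGFR", "PTEN", "AKT1", "STAT3",
    "BCL2", "CASP3", "FOXO3", "NOTCH1", "RB1", "CDK4", "MDM2", "ATG5",
    "BECN1", "SIRT1", "YAP1", "GPX4",
]
CELL_LINES = [
    "HeLa", "MCF-7", "A549", "HCT116", "PC-3", "U2OS", "HepG2", "SKOV3",
    "K562", "MDA-MB-231",
]
DRUGS = [
    "rapamycin", "erlotinib", "ABT-199", "nutlin-3", "staurosporine",
    "metformin", "doxorubicin", "etoposide",
]

PA_TEMPLATES: dict[str, list[str]] = {
    "gene loss-of-function": [
        "{g} knockout", "{g} -/-", "deletion of {g}",
        "CRISPR-mediated ablation of {g}",
    ],
    "gene gain-of-function": [
        "overexpression of {g}", "ectopic expression of {g}",
        "{g} transgene induction",
    ],
    "RNAi/knockdown": [
        "silencing {g} by siRNA", "knockdown of {g}",
        "shRNA-mediated depletion of {g}",
    ],
    "pharmacological inhibition": [
        "treatment with the {g} inhibitor {d}",
        "pharmacological inhibition of {g}",
    ],
    "pharmacological augmentation": [
        "treatment with the {g} agonist {d}",
        "pharmacological activation of {g}",
    ],
    "other": ["mutation of {g}", "expression of dominant-negative {g}"],
}

CONTEXT_TEMPLATES: dict[str, list[str]] = {
    "patient": ["patients", "breast cancer patients"],
    "organism": ["mice", "zebrafish", "nude mice"],
    "tissue/organ": ["liver", "lung tissue", "mammary epithelium"],
    "neoplasm": ["tumours", "primary tumours"],
    "graft": ["skin grafts", "allografts"],
    "xenograft": ["xenografts", "tumour xenografts"],
    "cells": ["{cl} cells", "primary fibroblasts", "keratinocytes"],
    "transformed cells": ["{cl} tumour cells", "transformed fibroblasts"],
    "organoid": ["intestinal organoids", "tumour organoids"],
    "in vitro": ["in vitro"],
    "in vivo": ["in vivo"],
}

EFFECT_TEMPLATES: dict[str, list[str]] = {
    "positive": ["induced", "promoted", "enhanced", "increased"],
    "negative": ["inhibited", "suppressed", "reduced", "impaired"],
    "regulates": ["regulated", "modulated"],
    "rescues": ["rescued", "restored"],
    "no effect": ["did not affect", "had no effect on"],
}

# phenotype surfaces default to the assertion term itself
PHENOTYPE_VARIANTS: dict[str, list[str]] = {
    "tumour-growth": ["tumour growth"],
    "cell cycle arrest": ["cell cycle arrest", "G1/S cell cycle arrest"],
    "epithelial-mesenchymal transition": [
        "epithelial-mesenchymal transition", "EMT",
    ],
}

DISTRACTOR_TEMPLATES = [
    "{Ph} is a regulated process that clears damaged cells from tissues.",
    "The role of {g} in {ph} remains poorly understood.",
    "{Ph} is a hallmark of cancer progression.",
    "Previous studies have implicated {g} in the regulation of {ph}.",
    "Aberrant {ph} contributes to tumour development in many settings.",
    "{g} is frequently mutated in human cancers.",
    "Here we investigated how {g} signalling shapes the response to stress.",
    "The molecular mechanisms coupling {g} to {ph} are incompletely defined.",
]


@dataclass
class SynthConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_docs: int = 100
    seed: int = 0
    experiments_per_doc: tuple[int, int] = (1, 3)
    groups_per_experiment: tuple[int, int] = (1, 4)
    p_multisentence: float = 0.3
    p_distractor: float = 0.4
    assertion_skew: float = 1.0  # power-law exponent over assertion ranks
    p_unlinked_extra: float = 0.15  # chance a block adds a marked, unlinked phenotype
    surface_variation: bool = True
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        for name in ("p_multisentence", "p_distractor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("experiments_per_doc", "groups_per_experiment"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}=({lo},{hi}) is not a non-empty range")
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = 0
        self.mentions: list[EntityMention] = []
        self.links: list[LinkGroup] = []

    def text(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def mention(self, surface: str, category: str, assertion: str) -> str:
        mid = f"{self.doc_id}-t{len(self.mentions)}"
        self.mentions.append(
            EntityMention(
                id=mid, category=category, assertion=assertion,
                start=self.pos, end=self.pos + len(surface), surface=surface,
            )
        )
        self.text(surface)
        return mid

    def link(self, pa: str, eff: str, ph: str, ctx: str) -> None:
        gid = f"{self.doc_id}-l{len(self.links)}"
        self.links.append(
            LinkGroup(
                id=gid,
                members={
                    PERTURBING_ACTION: pa, EFFECT: eff,
                    PHENOTYPE: ph, CONTEXT: ctx,
                },
            )
        )

    def build(self) -> AnnotatedDocument:
        return AnnotatedDocument(
            doc_id=self.doc_id, text="".join(self.parts),
            mentions=self.mentions, links=self.links,
        )


def _skewed_choice(rng: np.random.Generator, items: tuple[str, ...],
                   skew: float) -> str:
    ranks = np.arange(1, len(items) + 1, dtype=np.float64)
    w = ranks ** (-skew)
    return items[rng.choice(len(items), p=w / w.sum())]


def _pick(rng: np.random.Generator, options: list[str], vary: bool) -> str:
    return options[rng.integers(len(options))] if vary else options[0]


def generate_corpus(config: SynthConfig) -> list[AnnotatedDocument]:
    return generate_corpus_detailed(config)[0]


def generate_corpus_detailed(
    config: SynthConfig,
) -> tuple[list[AnnotatedDocument], dict]:
    """Generate documents plus exact generator bookkeeping.

    Bookkeeping counts are tallied as entities are emitted (not recounted
    from the documents), so they provide an independent total for the
    corpus-statistics round-trip check. ``gene_mentions`` records the
    character span of the gene symbol inside every perturbing-action
    phrase, for use as externally-supplied gene input in the case study.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    docs: list[AnnotatedDocument] = []
    book = {
        "n_docs": config.n_docs, "n_mentions": 0, "n_linked_mentions": 0,
        "n_link_groups": 0, "per_category": {c: 0 for c in schema.categories},
        "n_sentences": 0, "n_distractor_sentences": 0,
        "n_cross_sentence_groups": 0, "gene_mentions": [],
    }

    for d in range(config.n_docs):
        builder = _DocBuilder(f"synth{d}")
        sentences: list[tuple[str, object]] = []  # ("exp"|"dis", payload)
        n_exp = int(rng.integers(config.experiments_per_doc[0],
                                 config.experiments_per_doc[1] + 1))
        exp_sentences = 0
        experiments = []
        for _ in range(n_exp):
            exp = _plan_experiment(rng, config)
            experiments.append(exp)
            exp_sentences += len(exp)
        if config.p_distractor > 0:
            n_dis = int(round(
                config.p_distractor / (1 - config.p_distractor) * exp_sentences
            )) if config.p_distractor < 1 else 0
        else:
            n_dis = 0

        slots: list[tuple[str, object]] = []
        for exp in experiments:
            slots.append(("exp", exp))
        for _ in range(n_dis):
            slots.append(("dis", None))
        rng.shuffle(slots)

        for kind, payload in slots:
            if kind == "dis":
                _emit_distractor(builder, rng, config)
                book["n_sentences"] += 1
                book["n_distractor_sentences"] += 1
            else:
                cross = _emit_experiment(builder, rng, config, payload, book)
                book["n_sentences"] += len(payload)
                book["n_cross_sentence_groups"] += cross

        doc = builder.build()
        book["n_mentions"] += len(doc.mentions)
        book["n_linked_mentions"] += len(doc.linked_mention_ids())
        book["n_link_groups"] += len(doc.links)
        for m in doc.mentions:
            book["per_category"][m.category] += 1
        docs.append(doc)
    return docs, book


def _plan_experiment(rng: np.random.Generator, config: SynthConfig) -> list[dict]:
    """Plan the blocks of one experiment; one list entry per sentence."""
    schema = config.schema
    lo, hi = config.groups_per_experiment
    n_groups = int(rng.integers(lo, hi + 1))
    multisentence = rng.random() < config.p_multisentence
    if multisentence and n_groups < 2:
        n_groups = 2
    if n_groups >= 2 and (multisentence or rng.random() < 0.5):
        first = int(rng.integers(1, n_groups))
        block_sizes = [first, n_groups - first]
    else:
        block_sizes = [n_groups]

    blocks = []
    for size in block_sizes:
        blocks.append({
            "effect": _skewed_choice(rng, schema.assertions[EFFECT],
                                     config.assertion_skew),
            "context": _skewed_choice(rng, schema.assertions[CONTEXT],
                                      config.assertion_skew),
            "phenotypes": [
                _skewed_choice(rng, schema.assertions[PHENOTYPE],
                               config.assertion_skew)
                for _ in range(size)
            ],
        })
    if multisentence and len(blocks) == 2:
        return [[blocks[0]], [blocks[1]]]  # two sentences
    return [blocks]  # one sentence holding all blocks


def _surface_for(rng, config, category: str, assertion: str,
                 gene: str | None = None) -> tuple[str, int, int]:
    """Realise a surface; returns (surface, gene_start, gene_end) rel offsets."""
    vary = config.surface_variation
    if category == PERTURBING_ACTION:
        tpl = _pick(rng, PA_TEMPLATES[assertion], vary)
        g = gene or GENES[rng.integers(len(GENES))]
        d = DRUGS[rng.integers(len(DRUGS))]
        surface = tpl.format(g=g, d=d)
        gs = surface.index(g)
        return surface, gs, gs + len(g)
    if category == CONTEXT:
        tpl = _pick(rng, CONTEXT_TEMPLATES[assertion], vary)
        return tpl.format(cl=CELL_LINES[rng.integers(len(CELL_LINES))]), -1, -1
    if category == EFFECT:
        return _pick(rng, EFFECT_TEMPLATES[assertion], vary), -1, -1
    variants = PHENOTYPE_VARIANTS.get(assertion, [assertion])
    return _pick(rng, variants, vary), -1, -1


def _emit_experiment(builder: _DocBuilder, rng, config: SynthConfig,
                     sentence_plan: list[list[dict]], book: dict) -> int:
    """Realise one experiment; returns the number of cross-sentence groups."""
    gene = GENES[rng.integers(len(GENES))]
    pa_assertion = _skewed_choice(
        rng, config.schema.assertions[PERTURBING_ACTION], config.assertion_skew
    )
    pa_surface, gs, ge = _surface_for(
        rng, config, PERTURBING_ACTION, pa_assertion, gene=gene
    )
    pa_surface = pa_surface[0].upper() + pa_surface[1:]
    pa_start = builder.pos
    pa_id = builder.mention(pa_surface, PERTURBING_ACTION, pa_assertion)
    book["gene_mentions"].append(
        (builder.doc_id, pa_start + gs, pa_start + ge, gene)
    )
    cross_sentence_groups = 0

    for s_idx, blocks in enumerate(sentence_plan):
        if s_idx > 0:
            opener = ["It also ", "Moreover, it ", "In addition, it "][
                int(rng.integers(3))
            ]
            builder.text(" " + opener)
            cross = True
        else:
            builder.text(" ")
            cross = False
        for b_idx, block in enumerate(blocks):
            if b_idx > 0:
                builder.text(" and ")
            eff_surface, _, _ = _surface_for(rng, config, EFFECT, block["effect"])
            eff_id = builder.mention(eff_surface, EFFECT, block["effect"])
            builder.text(" ")
            ph_ids = []
            for p_idx, ph in enumerate(block["phenotypes"]):
                if p_idx > 0:
                    builder.text(" and ")
                ph_surface, _, _ = _surface_for(rng, config, PHENOTYPE, ph)
                ph_ids.append(builder.mention(ph_surface, PHENOTYPE, ph))
            builder.text(" in " if block["context"] not in ("in vitro", "in vivo")
                         else " ")
            ctx_surface, _, _ = _surface_for(rng, config, CONTEXT,
                                             block["context"])
            ctx_id = builder.mention(ctx_surface, CONTEXT, block["context"])
            if rng.random() < config.p_unlinked_extra:
                # a marked phenotype the annotator did not link to any group,
                # mirroring the real corpus where many marked entities are
                # never linked
                extra = _skewed_choice(
                    rng, config.schema.assertions[PHENOTYPE],
                    config.assertion_skew,
                )
                ex_surface, _, _ = _surface_for(rng, config, PHENOTYPE, extra)
                builder.text(" as well as ")
                builder.mention(ex_surface, PHENOTYPE, extra)
            for ph_id in ph_ids:
                builder.link(pa_id, eff_id, ph_id, ctx_id)
                if cross:
                    cross_sentence_groups += 1
        builder.text(". ")
    return cross_sentence_groups


def _emit_distractor(builder: _DocBuilder, rng, config: SynthConfig) -> None:
    tpl = DISTRACTOR_TEMPLATES[int(rng.integers(len(DISTRACTOR_TEMPLATES)))]
    ph = config.schema.assertions[PHENOTYPE][
        int(rng.integers(len(config.schema.assertions[PHENOTYPE])))
    ]
    sentence = tpl.format(
        g=GENES[rng.integers(len(GENES))], ph=ph,
        Ph=ph[0].upper() + ph[1:],
    )
    builder.text(sentence + " ")


def corpus_summary(docs: list[AnnotatedDocument],
                   schema: Schema = DEFAULT_SCHEMA) -> dict:
    """Realised structural statistics of a (generated or real) corpus."""
    from collections import Counter

    assertion_freq: Counter = Counter()
    groups_per_mention: Counter = Counter()
    n_groups = 0
    n_cross = 0
    n_sentences = 0
    n_unannotated_sentences = 0
    for doc in docs:
        sentences = split_sentences(doc.text)
        n_sentences += len(sentences)

        def sent_of(pos: int) -> int:
            for s, (a, b) in enumerate(sentences):
                if a <= pos < b:
                    return s
            return len(sentences) - 1

        covered = set()
        for m in doc.mentions:
            assertion_freq[(m.category, m.assertion)] += 1
            covered.add(sent_of(m.start))
        n_unannotated_sentences += len(sentences) - len(covered)
        by_id = {m.id: m for m in doc.mentions}
        for g in doc.links:
            n_groups += 1
            sents = {sent_of(by_id[mid].start) for mid in g.members.values()}
            if len(sents) > 1:
                n_cross += 1
            for mid in g.members.values():
                groups_per_mention[mid] += 1
    reuse = (
        sum(groups_per_mention.values()) / len(groups_per_mention)
        if groups_per_mention else 0.0
    )
    return {
        "assertion_freq": dict(assertion_freq),
        "n_link_groups": n_groups,
        "cross_sentence_link_fraction": n_cross / n_groups if n_groups else 0.0,
        "mean_groups_per_linked_mention": reuse,
        "max_groups_per_mention": max(groups_per_mention.values(), default=0),
        "unannotated_sentence_fraction": (
            n_unannotated_sentences / n_sentences if n_sentences else 0.0
        ),
    }
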