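"""Annotation schema: entity categories and their assertion vocabularies.

The corpus marks four categories of entity in experiment descriptions:

* **Perturbing action** — an experimental manipulation of a named gene
  (knockout, knockdown, overexpression, drug inhibition/augmentation).
* **Context** — the experimental model subjected to the perturbation
  (patients, organisms, tissues, cell lines, xenografts, ...).
* **Phenotype** — the induced change in cell or organism behaviour,
  restricted to a fixed vocabulary of cell-death, cancer and general
  cell-biology terms.
* **Effect** — the direction in which the phenotype is regulated.

Each marked entity carries exactly one *assertion*: a fine-grained label
drawn from its category's closed vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PERTURBING_ACTION = "PerturbingAction"
CONTEXT = "Context"
EFFECT = "Effect"
PHENOTYPE = "Phenotype"

CATEGORIES: tuple[str, ...] = (PERTURBING_ACTION, CONTEXT, EFFECT, PHENOTYPE)

_PERTURBING_ACTION_ASSERTIONS = (
    "gene loss-of-function",
    "gene gain-of-function",
    "RNAi/knockdown",
    "pharmacological inhibition",
    "pharmacological augmentation",
    "other",
)

_CONTEXT_ASSERTIONS = (
    "patient",
    "organism",
    "tissue/organ",
    "neoplasm",
    "graft",
    "xenograft",
    "cells",
    "transformed cells",
    "organoid",
    "in vitro",
    "in vivo",
)

_EFFECT_ASSERTIONS = (
    "positive",
    "negative",
    "regulates",
    "rescues",
    "no effect",
)

# 11 cell-death terms, 7 cancer terms, 13 general cell-biology terms.
_PHENOTYPE_ASSERTIONS = (
    "apoptosis",
    "anoikis",
    "autophagy",
    "cell death",
    "entosis",
    "ferroptosis",
    "mitophagy",
    "necroptosis",
    "necrosis",
    "oncosis",
    "pyroptosis",
    "metastasis",
    "transformation",
    "tumour-growth",
    "tumourigenesis",
    "tumour initiation",
    "tumour progression",
    "tumour regression",
    "adhesion",
    "cell cycle arrest",
    "cell growth",
    "cell survival",
    "colony formation",
    "differentiation",
    "epithelial-mesenchymal transition",
    "invasion",
    "migration",
    "proliferation",
    "quiescence",
    "self-renewal",
    "senescence",
)


@dataclass(frozen=True)
class Schema:
    """The closed annotation vocabulary: categories and per-category assertions.

    Invariants (checked in ``__post_init__``): the four categories are
    present in order, and assertion names are unique within a category.
    """

    categories: tuple[str, ...] = CATEGORIES
    assertions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            PERTURBING_ACTION: _PERTURBING_ACTION_ASSERTIONS,
            CONTEXT: _CONTEXT_ASSERTIONS,
            EFFECT: _EFFECT_ASSERTIONS,
            PHENOTYPE: _PHENOTYPE_ASSERTIONS,
        }
    )

    def __post_init__(self) -> None:
        for cat in self.categories:
            if cat not in self.assertions:
                raise ValueError(f"category {cat!r} has no assertion vocabulary")
            terms = self.assertions[cat]
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate assertions in category {cat!r}")

    def is_valid(self, category: str, assertion: str) -> bool:
        return category in self.assertions and assertion in self.assertions[category]

    def assertion_index(self, category: str, assertion: str) -> int:
        return self.assertions[category].index(assertion)


DEFAULT_SCHEMA = Schema()
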