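"""Extrinsic-evaluation aggregation: from predictions to per-gene records.

Externally produced gene mentions (e.g. from a dedicated gene-NER tool)
are joined to predicted perturbing actions by span overlap — every
annotated perturbing action contains a gene name, so containment is the
common case and overlap the fallback. Each (gene, perturbing-action)
attachment yields one record collecting the context, effect and
phenotype assertions of mentions pair-linked to that perturbing action.
Records with at least one of each ("complete quadruples") describe the
function of a gene in a specific experimental context; those are the
units counted in the in-vitro/in-vivo and cancer/non-cancer groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .documents import AnnotatedDocument, EntityMention
from .schema import CONTEXT, EFFECT, PERTURBING_ACTION, PHENOTYPE

__all__ = [
    "GeneMention",
    "CaseStudyRecord",
    "attach_genes",
    "build_records",
    "filter_complete",
    "context_grouping",
    "GROUPINGS",
]


@dataclass(frozen=True)
class GeneMention:
    doc_id: str
    start: int
    end: int
    symbol: str


@dataclass
class CaseStudyRecord:
    gene: str
    doc_id: str
    pa_mention_id: str
    pa_assertion: str
    contexts: set[str] = field(default_factory=set)
    effects: set[str] = field(default_factory=set)
    phenotypes: set[str] = field(default_factory=set)

    @property
    def complete(self) -> bool:
        return bool(self.contexts and self.effects and self.phenotypes)

    def rendered_contexts(self) -> str:
        """Multi-assertion combination label, e.g. ``"Cells; Organism"``."""
        return "; ".join(
            a[0].upper() + a[1:] for a in sorted(self.contexts)
        )


def attach_genes(
    doc: AnnotatedDocument, genes: list[GeneMention]
) -> tuple[list[tuple[GeneMention, EntityMention]], list[GeneMention]]:
    """Attach genes to perturbing-action mentions by span overlap.

    Returns (attachments, unattached). A gene attaches to every
    perturbing action whose span overlaps it; two genes inside one
    perturbing action both attach.
    """
    pas = [m for m in doc.mentions if m.category == PERTURBING_ACTION]
    attached: list[tuple[GeneMention, EntityMention]] = []
    unattached: list[GeneMention] = []
    for g in genes:
        if g.doc_id != doc.doc_id:
            continue
        hits = [
            pa for pa in pas if g.start < pa.end and pa.start < g.end
        ]
        if hits:
            attached.extend((g, pa) for pa in hits)
        else:
            unattached.append(g)
    return attached, unattached


def build_records(
    docs: list[AnnotatedDocument],
    genes: list[GeneMention],
    links: dict[str, set[frozenset[str]]],
) -> list[CaseStudyRecord]:
    """One record per (gene, perturbing-action) attachment.

    ``links`` maps doc_id to the predicted set of unordered mention-id
    pairs. The record's assertion sets are those of mentions pair-linked
    to the perturbing action, by category.
    """
    records: list[CaseStudyRecord] = []
    genes_by_doc: dict[str, list[GeneMention]] = {}
    for g in genes:
        genes_by_doc.setdefault(g.doc_id, []).append(g)
    for doc in docs:
        attached, _ = attach_genes(doc, genes_by_doc.get(doc.doc_id, []))
        by_id = {m.id: m for m in doc.mentions}
        doc_links = links.get(doc.doc_id, set())
        for gene, pa in attached:
            rec = CaseStudyRecord(
                gene=gene.symbol, doc_id=doc.doc_id,
                pa_mention_id=pa.id, pa_assertion=pa.assertion,
            )
            for pair in doc_links:
                if pa.id not in pair:
                    continue
                (other_id,) = set(pair) - {pa.id}
                other = by_id.get(other_id)
                if other is None:
                    continue
                if other.category == CONTEXT:
                    rec.contexts.add(other.assertion)
                elif other.category == EFFECT:
                    rec.effects.add(other.assertion)
                elif other.category == PHENOTYPE:
                    rec.phenotypes.add(other.assertion)
            records.append(rec)
    return records


def filter_complete(records: list[CaseStudyRecord]) -> list[CaseStudyRecord]:
    """Keep records with >=1 context, >=1 effect and >=1 phenotype."""
    return [r for r in records if r.complete]


GROUPINGS: dict[str, tuple[tuple[str, frozenset[str]], tuple[str, frozenset[str]]]] = {
    "invitro_invivo": (
        ("in vitro", frozenset({"cells", "transformed cells", "in vitro",
                                "organoid"})),
        ("in vivo", frozenset({"organism", "neoplasm", "tissue/organ",
                               "in vivo", "xenograft"})),
    ),
    "cancer_noncancer": (
        ("non-cancer", frozenset({"organism", "tissue/organ", "cells",
                                  "organoid", "in vitro", "in vivo"})),
        ("cancer", frozenset({"transformed cells", "neoplasm", "xenograft"})),
    ),
}


def context_grouping(
    records: list[CaseStudyRecord],
    phenotype: str | None = None,
    grouping: str = "invitro_invivo",
) -> dict:
    """Count records by context-assertion class, with overlap.

    ``phenotype`` filters records to those whose phenotype set contains
    the given assertion (e.g. ``"apoptosis"``). A record counts in a
    group if any of its context assertions belongs to that group's list;
    context assertions in neither list (e.g. ``patient`` and ``graft``)
    are collected in an explicit ``unclassified`` bucket, never dropped
    silently.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    (name_a, set_a), (name_b, set_b) = GROUPINGS[grouping]
    known = set_a | set_b
    selected = [
        r for r in records
        if phenotype is None or phenotype in r.phenotypes
    ]
    in_a = in_b = overlap = unclassified_only = 0
    unclassified_assertions: set[str] = set()
    for r in selected:
        a = bool(r.contexts & set_a)
        b = bool(r.contexts & set_b)
        stray = r.contexts - known
        unclassified_assertions |= stray
        in_a += a
        in_b += b
        overlap += a and b
        if not a and not b:
            unclassified_only += 1
    assert in_a + in_b - overlap <= len(selected)
    return {
        "total": len(selected),
        name_a: in_a,
        name_b: in_b,
        "overlap": overlap,
        "unclassified": unclassified_only,
        "unclassified_assertions": sorted(unclassified_assertions),
    }
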