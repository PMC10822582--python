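"""Domain types for annotated abstracts and their validation.

Character spans are 0-based half-open ``[start, end)`` into the document
text throughout the package; readers of external formats convert to this
convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Iterable

from .schema import CATEGORIES, DEFAULT_SCHEMA, Schema

__all__ = [
    "EntityMention",
    "LinkGroup",
    "AnnotatedDocument",
    "CorpusStats",
    "validate",
    "corpus_stats",
]


@dataclass(frozen=True)
class EntityMention:
    """A contiguous character span carrying a category and an assertion."""

    id: str
    category: str
    assertion: str
    start: int
    end: int
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class LinkGroup:
    """Four entities, one per category, jointly describing one experiment."""

    id: str
    members: dict[str, str]  # category -> mention id

    def mention_ids(self) -> tuple[str, ...]:
        return tuple(self.members[c] for c in CATEGORIES if c in self.members)


@dataclass
class AnnotatedDocument:
    """One abstract's text plus its entity mentions and link groups."""

    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    links: list[LinkGroup] = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise KeyError(mention_id)

    def linked_mention_ids(self) -> set[str]:
        out: set[str] = set()
        for g in self.links:
            out.update(g.members.values())
        return out

    def linked_pairs(self) -> set[frozenset[str]]:
        """Unordered pairs of distinct mention ids co-occurring in >=1 group."""
        pairs: set[frozenset[str]] = set()
        for g in self.links:
            ids = list(g.members.values())
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if ids[i] != ids[j]:
                        pairs.add(frozenset((ids[i], ids[j])))
        return pairs

    def copy_without_annotations(self) -> "AnnotatedDocument":
        return AnnotatedDocument(doc_id=self.doc_id, text=self.text)


@dataclass
class CorpusStats:
    """Corpus-level entity bookkeeping.

    ``n_linked_mentions`` counts mentions that appear in at least one link
    group, each counted once regardless of how many groups reuse it.
    """

    n_docs: int = 0
    n_mentions: int = 0
    n_linked_mentions: int = 0
    n_link_groups: int = 0
    per_category: Counter = field(default_factory=Counter)
    per_assertion: Counter = field(default_factory=Counter)  # (category, assertion)

    def __add__(self, other: "CorpusStats") -> "CorpusStats":
        return CorpusStats(
            n_docs=self.n_docs + other.n_docs,
            n_mentions=self.n_mentions + other.n_mentions,
            n_linked_mentions=self.n_linked_mentions + other.n_linked_mentions,
            n_link_groups=self.n_link_groups + other.n_link_groups,
            per_category=self.per_category + other.per_category,
            per_assertion=self.per_assertion + other.per_assertion,
        )


def validate(doc: AnnotatedDocument, schema: Schema = DEFAULT_SCHEMA) -> list[str]:
    """Return a list of invariant violations (empty iff the document is valid).

    Violations are data, not exceptions: each string names the offending
    mention/link ids and the invariant broken.
    """
    violations: list[str] = []
    n = len(doc.text)
    ids_seen: set[str] = set()
    by_id: dict[str, EntityMention] = {}

    for m in doc.mentions:
        if m.id in ids_seen:
            violations.append(f"mention {m.id}: duplicate id")
        ids_seen.add(m.id)
        by_id[m.id] = m
        if not (0 <= m.start < m.end <= n):
            violations.append(
                f"mention {m.id}: span [{m.start},{m.end}) empty or outside "
                f"document bounds [0,{n})"
            )
            continue
        if doc.text[m.start : m.end] != m.surface:
            violations.append(
                f"mention {m.id}: surface {m.surface!r} != text at span "
                f"{doc.text[m.start:m.end]!r}"
            )
        if m.category not in schema.categories:
            violations.append(f"mention {m.id}: unknown category {m.category!r}")
        elif not schema.is_valid(m.category, m.assertion):
            violations.append(
                f"mention {m.id}: assertion {m.assertion!r} not in the "
                f"{m.category} vocabulary"
            )

    sorted_mentions = sorted(doc.mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(sorted_mentions, sorted_mentions[1:]):
        if b.start < a.end:
            violations.append(
                f"mentions {a.id} and {b.id}: overlapping spans "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )

    link_ids: set[str] = set()
    for g in doc.links:
        if g.id in link_ids:
            violations.append(f"link {g.id}: duplicate id")
        link_ids.add(g.id)
        cats = sorted(g.members)
        if cats != sorted(CATEGORIES):
            violations.append(
                f"link {g.id}: members cover categories {cats}, "
                f"need exactly one of each of {sorted(CATEGORIES)}"
            )
        for cat, mid in g.members.items():
            if mid not in by_id:
                violations.append(f"link {g.id}: member {mid!r} is not a mention id")
            elif cat in CATEGORIES and by_id[mid].category != cat:
                violations.append(
                    f"link {g.id}: member {mid} has category {by_id[mid].category}, "
                    f"listed under {cat}"
                )
    return violations


def corpus_stats(corpus: Iterable[AnnotatedDocument]) -> CorpusStats:
    stats = CorpusStats()
    for doc in corpus:
        stats.n_docs += 1
        stats.n_mentions += len(doc.mentions)
        stats.n_linked_mentions += len(doc.linked_mention_ids())
        stats.n_link_groups += len(doc.links)
        for m in doc.mentions:
            stats.per_category[m.category] += 1
            stats.per_assertion[(m.category, m.assertion)] += 1
    return stats
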