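"""Readers/writers for standoff-annotated abstracts.

Two formats are supported:

* **Standoff XML** in the style of the MAE annotation tool: a ``<TEXT>``
  element holding the raw abstract, extent tags named after their entity
  category carrying ``id``, ``spans`` and ``text`` attributes plus the
  assertion, and ``<LINK>`` tags whose ``<Category>ID`` attributes name one
  member mention per category.
* **JSON interchange**: one object per document with ``doc_id``, ``text``,
  ``mentions`` and ``links``; the schema is frozen in ``docs/formats.md``.

Span convention: external ``spans="start~end"`` attributes are 0-based
half-open, identical to the in-memory convention, so the reader performs no
offset arithmetic; this is the single place where that equivalence is
asserted (``surface == text[start:end]`` is re-checked on read).
Discontinuous spans (comma-separated extents) are rejected: the schema
marks contiguous phrases only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from lxml import etree

from .documents import AnnotatedDocument, EntityMention, LinkGroup, validate
from .schema import CATEGORIES, DEFAULT_SCHEMA, Schema

__all__ = [
    "StandoffFormatError",
    "read_standoff_xml",
    "write_standoff_xml",
    "read_json",
    "write_json",
    "read_json_corpus",
    "write_json_corpus",
]


class StandoffFormatError(ValueError):
    """Malformed or schema-violating standoff input."""


_CATEGORY_ALIASES = {
    "perturbingaction": "PerturbingAction",
    "perturbing_action": "PerturbingAction",
    "context": "Context",
    "effect": "Effect",
    "phenotype": "Phenotype",
}

_ASSERTION_ATTRS = ("assertion", "label", "type")


def _normalise_category(tag_name: str) -> str | None:
    return _CATEGORY_ALIASES.get(tag_name.replace("-", "_").lower())


def _parse_spans(raw: str, tag_id: str) -> tuple[int, int]:
    if "," in raw:
        raise StandoffFormatError(
            f"tag {tag_id}: discontinuous span {raw!r} (contiguous phrases only)"
        )
    try:
        start_s, end_s = raw.split("~")
        return int(start_s), int(end_s)
    except ValueError as exc:
        raise StandoffFormatError(f"tag {tag_id}: malformed spans {raw!r}") from exc


def read_standoff_xml(
    path: str | Path, schema: Schema = DEFAULT_SCHEMA, doc_id: str | None = None
) -> AnnotatedDocument:
    """Parse one standoff XML file into a validated :class:`AnnotatedDocument`."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise StandoffFormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    text_el = root.find("TEXT")
    if text_el is None or text_el.text is None:
        raise StandoffFormatError(f"{path}: missing TEXT element")
    text = text_el.text

    mentions: list[EntityMention] = []
    links: list[LinkGroup] = []
    tags_parent = root.find("TAGS")
    elements = list(tags_parent) if tags_parent is not None else []

    for el in elements:
        if not isinstance(el.tag, str):
            continue
        if el.tag.upper() == "LINK":
            links.append(_parse_link(el))
            continue
        category = _normalise_category(el.tag)
        if category is None:
            raise StandoffFormatError(
                f"tag {el.get('id', '?')}: unknown extent tag <{el.tag}>"
            )
        tag_id = el.get("id")
        if tag_id is None:
            raise StandoffFormatError(f"<{el.tag}> extent tag without id")
        spans_attr = el.get("spans")
        if spans_attr is None:
            raise StandoffFormatError(f"tag {tag_id}: missing spans attribute")
        start, end = _parse_spans(spans_attr, tag_id)
        assertion = next(
            (el.get(a) for a in _ASSERTION_ATTRS if el.get(a) is not None), None
        )
        if assertion is None:
            raise StandoffFormatError(f"tag {tag_id}: missing assertion attribute")
        if not schema.is_valid(category, assertion):
            raise StandoffFormatError(
                f"tag {tag_id}: assertion {assertion!r} is not in the "
                f"{category} vocabulary"
            )
        mentions.append(
            EntityMention(
                id=tag_id,
                category=category,
                assertion=assertion,
                start=start,
                end=end,
                surface=el.get("text", text[start:end]),
            )
        )

    doc = AnnotatedDocument(
        doc_id=doc_id or path.stem, text=text, mentions=mentions, links=links
    )
    violations = validate(doc, schema)
    if violations:
        raise StandoffFormatError(f"{path}: " + "; ".join(violations))
    return doc


def _parse_link(el: etree._Element) -> LinkGroup:
    link_id = el.get("id")
    if link_id is None:
        raise StandoffFormatError("LINK tag without id")
    members: dict[str, str] = {}
    for attr, value in el.attrib.items():
        if attr.lower().endswith("id") and attr.lower() != "id":
            category = _normalise_category(attr[:-2])
            if category is not None:
                members[category] = value
    if not members:
        raise StandoffFormatError(f"link {link_id}: no member attributes")
    return LinkGroup(id=link_id, members=members)


def write_standoff_xml(doc: AnnotatedDocument, path: str | Path) -> None:
    root = etree.Element("FunctionalGenomicsTask")
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(doc.text)
    tags_el = etree.SubElement(root, "TAGS")
    for m in doc.mentions:
        el = etree.SubElement(tags_el, m.category)
        el.set("id", m.id)
        el.set("spans", f"{m.start}~{m.end}")
        el.set("text", m.surface)
        el.set("assertion", m.assertion)
    for g in doc.links:
        el = etree.SubElement(tags_el, "LINK")
        el.set("id", g.id)
        for category, mid in g.members.items():
            el.set(f"{category}ID", mid)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# --- JSON interchange -------------------------------------------------------

_REQUIRED_DOC_KEYS = ("doc_id", "text", "mentions", "links")
_REQUIRED_MENTION_KEYS = ("id", "category", "assertion", "start", "end", "surface")


def doc_to_dict(doc: AnnotatedDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "mentions": [
            {
                "id": m.id,
                "category": m.category,
                "assertion": m.assertion,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
            }
            for m in doc.mentions
        ],
        "links": [{"id": g.id, "members": dict(g.members)} for g in doc.links],
    }


def doc_from_dict(obj: dict, schema: Schema = DEFAULT_SCHEMA) -> AnnotatedDocument:
    for key in _REQUIRED_DOC_KEYS:
        if key not in obj:
            raise StandoffFormatError(f"document object missing key {key!r}")
    mentions = []
    for m in obj["mentions"]:
        for key in _REQUIRED_MENTION_KEYS:
            if key not in m:
                raise StandoffFormatError(
                    f"mention object {m.get('id', '?')} missing key {key!r}"
                )
        mentions.append(
            EntityMention(
                id=m["id"],
                category=m["category"],
                assertion=m["assertion"],
                start=int(m["start"]),
                end=int(m["end"]),
                surface=m["surface"],
            )
        )
    links = []
    for g in obj["links"]:
        if "id" not in g or "members" not in g:
            raise StandoffFormatError("link object missing 'id' or 'members'")
        links.append(LinkGroup(id=g["id"], members=dict(g["members"])))
    doc = AnnotatedDocument(
        doc_id=obj["doc_id"], text=obj["text"], mentions=mentions, links=links
    )
    violations = validate(doc, schema)
    if violations:
        raise StandoffFormatError("; ".join(violations))
    return doc


def write_json(doc: AnnotatedDocument) -> str:
    return json.dumps(doc_to_dict(doc), ensure_ascii=False, indent=2)


def read_json(text: str, schema: Schema = DEFAULT_SCHEMA) -> AnnotatedDocument:
    return doc_from_dict(json.loads(text), schema)


def write_json_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write a corpus as JSON Lines, one document object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc_to_dict(doc), ensure_ascii=False) + "\n")


def read_json_corpus(
    path: str | Path, schema: Schema = DEFAULT_SCHEMA
) -> list[AnnotatedDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(doc_from_dict(json.loads(line), schema))
    return docs
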