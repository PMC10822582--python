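"""Loading and checking a locally available copy of the released corpus.

The annotated corpus of 800 abstracts is distributed at
https://github.com/cambridgeltl/functional-genomics-ie. This module
never downloads anything: point :func:`load_corpus_dir` at a local
checkout (XML standoff files and/or JSON-lines interchange files) and
it returns validated documents. :func:`released_corpus_checks` then
recomputes the corpus-level reference quantities: 10 458 marked
entities, 4 697 linked entities, and a sentence-co-occurrence baseline
linking F1 of ~0.42 (the exact value shifts slightly with the sentence
splitter).
"""

from __future__ import annotations

from pathlib import Path

from .documents import AnnotatedDocument, corpus_stats
from .evaluation import cooccurrence_baseline, corpus_linking_prf
from .standoff import read_json_corpus, read_standoff_xml

__all__ = ["load_corpus_dir", "released_corpus_checks"]


def load_corpus_dir(path: str | Path) -> list[AnnotatedDocument]:
    """Load every standoff XML / JSON-lines file under ``path``."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(
            f"corpus directory {path} not found; place a local copy of the "
            "released corpus there (no download is performed)"
        )
    docs: list[AnnotatedDocument] = []
    for xml_file in sorted(path.rglob("*.xml")):
        docs.append(read_standoff_xml(xml_file))
    for jsonl_file in sorted(path.rglob("*.jsonl")):
        docs.extend(read_json_corpus(jsonl_file))
    if not docs:
        raise FileNotFoundError(f"no .xml or .jsonl corpus files under {path}")
    return docs


def released_corpus_checks(docs: list[AnnotatedDocument]) -> dict:
    """Recompute the corpus-level reference quantities from loaded documents."""
    stats = corpus_stats(docs)
    baseline = corpus_linking_prf(docs, cooccurrence_baseline)
    return {
        "n_docs": stats.n_docs,
        "n_mentions": stats.n_mentions,
        "n_linked_mentions": stats.n_linked_mentions,
        "baseline_precision": baseline.precision,
        "baseline_recall": baseline.recall,
        "baseline_f1": baseline.f1,
    }
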