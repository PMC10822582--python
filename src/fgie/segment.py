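"""Word and sentence segmentation.

Words are whitespace-delimited chunks with sentence punctuation split off
at the edges; symbol runs such as the knockout notation ``-/-`` survive as
single words. Sentence splitting is rule based with abbreviation handling
and is pluggable wherever it is consumed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable

logger = logging.getLogger(__name__)

__all__ = ["Word", "segment_words", "split_sentences", "snap_span_to_words"]


@dataclass(frozen=True)
class Word:
    start: int
    end: int
    surface: str


_EDGE_PUNCT = ".,;:!?()[]{}\"'"
_WS_CHUNK = re.compile(r"\S+")


def segment_words(text: str) -> list[Word]:
    """Segment ``text`` into words with character offsets.

    Concatenating the words with their gaps reconstructs the text exactly;
    leading/trailing punctuation of a whitespace chunk becomes separate
    single-character words, interior symbols are kept.
    """
    words: list[Word] = []
    for match in _WS_CHUNK.finditer(text):
        start, end = match.start(), match.end()
        # peel leading punctuation
        while start < end - 1 and text[start] in _EDGE_PUNCT:
            words.append(Word(start, start + 1, text[start]))
            start += 1
        # peel trailing punctuation (emit after the core, in order)
        trailing: list[Word] = []
        while end - 1 > start and text[end - 1] in _EDGE_PUNCT:
            trailing.append(Word(end - 1, end, text[end - 1]))
            end -= 1
        words.append(Word(start, end, text[start:end]))
        words.extend(reversed(trailing))
    return words


_ABBREVIATIONS = {
    "e.g.", "i.e.", "cf.", "vs.", "al.", "fig.", "figs.", "ref.", "refs.",
    "dr.", "no.", "approx.", "ca.", "etc.", "resp.",
}

_SENT_BOUNDARY = re.compile(r"[.!?]+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return sentence spans ``[start, end)`` covering all of ``text``.

    A ``.!?`` run ends a sentence when followed by whitespace and an
    upper-case letter or digit, unless the preceding token is a known
    abbreviation or a single capital initial.
    """
    boundaries: list[int] = []
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.end()
        if end >= len(text):
            continue
        rest = text[end:]
        stripped = rest.lstrip()
        if stripped == rest:  # no whitespace after the punctuation
            continue
        if not stripped or not (stripped[0].isupper() or stripped[0].isdigit()):
            continue
        prev = text[: match.start()].rsplit(None, 1)
        prev_tok = (prev[-1] if prev else "") + text[match.start() : end]
        low = prev_tok.lower()
        if low in _ABBREVIATIONS:
            continue
        if re.fullmatch(r"[A-Z]\.", prev_tok):
            continue
        boundaries.append(end)
    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        spans.append((start, b))
        start = b
    if start < len(text):
        spans.append((start, len(text)))
    elif not spans and text:
        spans.append((0, len(text)))
    return spans


SentenceSplitter = Callable[[str], list[tuple[int, int]]]


def snap_span_to_words(
    start: int, end: int, words: list[Word], context: str = ""
) -> tuple[int, int]:
    """Snap a character span outward to the nearest word boundaries.

    Spans that already coincide with word boundaries are returned
    unchanged; otherwise a warning is logged and the span is widened to
    cover every word it touches.
    """
    new_start, new_end = start, end
    for w in words:
        if w.start < start < w.end:
            new_start = w.start
        if w.start < end < w.end:
            new_end = w.end
    if (new_start, new_end) != (start, end):
        logger.warning(
            "span [%d,%d) does not align to word boundaries%s; snapped to [%d,%d)",
            start, end, f" in {context}" if context else "", new_start, new_end,
        )
    return new_start, new_end
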