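"""Narrative pre-processing and matching primitives.

Pipeline: section isolation -> sentence segmentation -> word tokenization
-> case-insensitive dictionary tagging -> same-sentence proximity matching.

Tokenization splits on whitespace and keeps word tokens only: leading and
trailing punctuation is discarded, internal hyphens and apostrophes are
kept ("re-used", "patient's"). Punctuation therefore never counts as a
word when measuring the gap between two tagged spans, which is what the
"<= N words apart" proximity rule requires. All matching is done on
case-folded token text; span positions are invariant under case changes
of the input.

Sentence segmentation is rule-based and deterministic: a sentence ends at
``.``, ``!`` or ``?`` followed by whitespace and an uppercase letter or
digit, guarded by a short abbreviation allowlist. Safety-report narratives
are template-like prose; this is adequate and dependency-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_model import ICSRRecord, Lexicon, normalize_text

__all__ = [
    "Token",
    "Sentence",
    "TagSpan",
    "tokenize_words",
    "segment_sentences",
    "isolate_sections",
    "tag",
    "proximity_match",
    "sentences_of_record",
]


@dataclass(frozen=True)
class Token:
    """One word token with half-open character offsets into the section text."""

    surface: str
    folded: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence, addressable as (record, section, index)."""

    record_id: str
    section_name: str
    index: int
    tokens: tuple[Token, ...]

    def folded_tokens(self) -> tuple[str, ...]:
        return tuple(tok.folded for tok in self.tokens)


@dataclass(frozen=True)
class TagSpan:
    """A dictionary match: half-open token range within one sentence."""

    record_id: str
    section_name: str
    sentence_index: int
    token_start: int
    token_end: int
    lexicon_name: str
    matched_phrase: str

    def __post_init__(self) -> None:
        if self.token_end <= self.token_start:
            raise ValueError("empty tag span")

    @property
    def sentence_key(self) -> tuple[str, str, int]:
        return (self.record_id, self.section_name, self.sentence_index)


# A word: runs of word characters, optionally glued by internal
# hyphen/apostrophe ("mix-up", "patient's"). Underscore counts as a word
# character here; it never occurs in narrative text.
_WORD_RE = re.compile(r"\w+(?:['’\-]\w+)*")

# Sentence terminator followed by whitespace then uppercase/digit.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")

# Tokens ending in '.' that do not terminate a sentence.
_ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "etc", "dr", "mr", "mrs", "ms", "approx", "vs", "inc", "no"}
)


def tokenize_words(text: str, already_normalized: bool = False) -> list[Token]:
    """Split ``text`` into word tokens with character offsets.

    Offsets index the NFKC-normalized, glyph-stripped text (normalisation
    is applied here unless the caller already did it).
    """
    if not already_normalized:
        text = normalize_text(text)
    return [
        Token(
            surface=m.group(),
            folded=m.group().casefold(),
            char_start=m.start(),
            char_end=m.end(),
        )
        for m in _WORD_RE.finditer(text)
    ]


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences in normalized text."""
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()
        # Guard: "e.g. Something" — check the word preceding the terminator.
        preceding = text[start:match.start()]
        last_word = preceding.rsplit(None, 1)[-1].casefold() if preceding.split() else ""
        last_word = last_word.rstrip(".")
        if last_word in _ABBREVIATIONS:
            continue
        spans.append((start, end))
        rest = text[end:]
        start = end + (len(rest) - len(rest.lstrip()))
    if start < len(text) and text[start:].strip():
        spans.append((start, len(text)))
    return spans


def segment_sentences(text: str, record_id: str = "", section_name: str = "") -> list[Sentence]:
    """Deterministically segment ``text`` into tokenized sentences.

    Empty or whitespace-only text yields an empty list. Character offsets
    are relative to the full normalized section text.
    """
    text = normalize_text(text)
    sentences: list[Sentence] = []
    for span_start, span_end in _sentence_spans(text):
        tokens = tuple(
            Token(t.surface, t.folded, t.char_start + span_start, t.char_end + span_start)
            for t in tokenize_words(text[span_start:span_end], already_normalized=True)
        )
        if tokens:
            sentences.append(
                Sentence(record_id, section_name, len(sentences), tokens)
            )
    return sentences


def isolate_sections(
    record: ICSRRecord, exclude_names: Iterable[str] = ()
) -> list[tuple[str, str]]:
    """Drop sections whose name matches any exclude pattern.

    Matching is case-insensitive substring: exclude pattern "analysis"
    removes a section named "Analysis Results". Order is preserved. A
    record whose sections are all excluded simply contributes no text.
    """
    patterns = [p.casefold() for p in exclude_names]
    return [
        (name, text)
        for name, text in record.sections
        if not any(p in name.casefold() for p in patterns)
    ]


def sentences_of_record(
    record: ICSRRecord, exclude_sections: Iterable[str] = ()
) -> list[Sentence]:
    """All sentences of a record's retained sections."""
    sentences: list[Sentence] = []
    for name, text in isolate_sections(record, exclude_sections):
        sentences.extend(segment_sentences(text, record.id, name))
    return sentences


def tag(sentences: Sequence[Sentence], lexicon: Lexicon) -> list[TagSpan]:
    """All maximal matches of lexicon phrases against folded token text.

    Longest match wins at each position and matching resumes after the
    matched span, so spans from one lexicon never overlap. Matching is
    case-insensitive by construction (folded tokens vs folded phrases).
    """
    phrase_set = lexicon.phrase_set
    max_len = lexicon.max_len
    spans: list[TagSpan] = []
    for sentence in sentences:
        folded = sentence.folded_tokens()
        i = 0
        n = len(folded)
        while i < n:
            matched = 0
            for length in range(min(max_len, n - i), 0, -1):
                if folded[i:i + length] in phrase_set:
                    matched = length
                    break
            if matched:
                spans.append(
                    TagSpan(
                        record_id=sentence.record_id,
                        section_name=sentence.section_name,
                        sentence_index=sentence.index,
                        token_start=i,
                        token_end=i + matched,
                        lexicon_name=lexicon.name,
                        matched_phrase=" ".join(folded[i:i + matched]),
                    )
                )
                i += matched
            else:
                i += 1
    return spans


def span_gap(a: TagSpan, b: TagSpan) -> int | None:
    """Word tokens strictly between the nearest edges of two same-sentence spans.

    Adjacent spans have gap 0; overlapping spans also count as gap 0.
    Returns None for spans in different sentences (or different
    sections/records).
    """
    if a.sentence_key != b.sentence_key:
        return None
    if a.token_start > b.token_start:
        a, b = b, a
    return max(0, b.token_start - a.token_end)


def proximity_match(
    anchor_spans: Sequence[TagSpan],
    positive_spans: Sequence[TagSpan],
    max_gap: int = 8,
) -> list[tuple[TagSpan, TagSpan]]:
    """Pairs (anchor, positive) in the same sentence separated by <= max_gap words.

    The gap is the count of word tokens strictly between the two spans'
    nearest edges; "equal or less than" makes the bound inclusive.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_sentence: dict[tuple[str, str, int], list[TagSpan]] = {}
    for span in positive_spans:
        by_sentence.setdefault(span.sentence_key, []).append(span)
    pairs: list[tuple[TagSpan, TagSpan]] = []
    for anchor in anchor_spans:
        for positive in by_sentence.get(anchor.sentence_key, ()):
            gap = span_gap(anchor, positive)
            if gap is not None and gap <= max_gap:
                pairs.append((anchor, positive))
    return pairs
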