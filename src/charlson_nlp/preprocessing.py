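"""Text normalization, tokenization and section detection.

Normalization lowercases, strips diacritics and standardizes typographic
quotes through an explicit per-character table so that every normalized
character traces back to the raw character that produced it.  Spans reported
by downstream modules always index the raw text through this map.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

# Explicit character table.  Multi-character expansions (ligatures) map every
# produced character back to the single source character.
_CHAR_TABLE: dict[str, str] = {}


def _fill(table: dict[str, str], chars: str, repl: str) -> None:
    for c in chars:
        table[c] = repl


_fill(_CHAR_TABLE, "àâäáãå", "a")
_fill(_CHAR_TABLE, "ÀÂÄÁÃÅ", "a")
_fill(_CHAR_TABLE, "éèêë", "e")
_fill(_CHAR_TABLE, "ÉÈÊË", "e")
_fill(_CHAR_TABLE, "îïíì", "i")
_fill(_CHAR_TABLE, "ÎÏÍÌ", "i")
_fill(_CHAR_TABLE, "ôöóòõ", "o")
_fill(_CHAR_TABLE, "ÔÖÓÒÕ", "o")
_fill(_CHAR_TABLE, "ûüúù", "u")
_fill(_CHAR_TABLE, "ÛÜÚÙ", "u")
_fill(_CHAR_TABLE, "ÿý", "y")
_fill(_CHAR_TABLE, "çÇ", "c")
_fill(_CHAR_TABLE, "ñÑ", "n")
_CHAR_TABLE["œ"] = "oe"
_CHAR_TABLE["Œ"] = "oe"
_CHAR_TABLE["æ"] = "ae"
_CHAR_TABLE["Æ"] = "ae"
# Typographic quotes and dashes.
_fill(_CHAR_TABLE, "«»“”„", '"')
_fill(_CHAR_TABLE, "‘’‚", "'")
_fill(_CHAR_TABLE, "–—", "-")
_CHAR_TABLE[" "] = " "  # no-break space


@dataclass(frozen=True)
class NormalizedText:
    """Normalized text plus the normalized-index → raw-index map."""

    norm: str
    norm_to_raw: tuple[int, ...]
    raw_len: int

    def raw_span(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span on the normalized text to raw coordinates."""
        if start == end:
            raw = self.norm_to_raw[start] if start < len(self.norm) else self.raw_len
            return (raw, raw)
        return (self.norm_to_raw[start], self.norm_to_raw[end - 1] + 1)


def normalize_text(raw: str) -> NormalizedText:
    """Lowercase, de-accent and standardize quotes, keeping an offset map."""
    out: list[str] = []
    mapping: list[int] = []
    for i, ch in enumerate(raw):
        repl = _CHAR_TABLE.get(ch)
        if repl is None:
            low = ch.lower()
            # Guard against the rare one-to-many lowercase expansions
            # (e.g. 'İ'); keep the char as-is so the map stays one-to-one
            # unless the table says otherwise.
            repl = low if len(low) == 1 else ch
        out.append(repl)
        mapping.extend([i] * len(repl))
    return NormalizedText(norm="".join(out), norm_to_raw=tuple(mapping), raw_len=len(raw))


@dataclass(frozen=True)
class Token:
    surface: str
    span_norm: tuple[int, int]
    index: int


# Word runs keep a trailing apostrophe (French elision: "l'asthme" →
# "l'" + "asthme"); any other non-space character is its own token.
_TOKEN_RE = re.compile(r"\w+'|\w+|[^\w\s]")


def tokenize(norm_text: NormalizedText | str) -> list[Token]:
    """Whitespace/punctuation tokenizer over normalized text."""
    text = norm_text.norm if isinstance(norm_text, NormalizedText) else norm_text
    return [
        Token(surface=m.group(0), span_norm=(m.start(), m.end()), index=i)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    ]


@dataclass(frozen=True)
class Section:
    title: str
    span_norm: tuple[int, int]
    relevance: str  # relevant | irrelevant | family_history


@dataclass(frozen=True)
class SectionLexiconEntry:
    pattern: str
    relevance: str


def detect_sections(
    norm_text: NormalizedText,
    lexicon: Iterable[SectionLexiconEntry],
) -> list[Section]:
    """Split the note at recognized section titles.

    Each matched title opens a section running to the next title (or end of
    note).  Overlapping title matches are resolved longest-match-at-position.
    Text before the first title forms one implicit relevant section.
    """
    text = norm_text.norm
    compiled = [(re.compile(e.pattern), e.relevance) for e in lexicon]
    hits: dict[int, tuple[int, str, str]] = {}  # start -> (end, title, relevance)
    for rx, relevance in compiled:
        for m in rx.finditer(text):
            prev = hits.get(m.start())
            if prev is None or m.end() > prev[0]:
                hits[m.start()] = (m.end(), m.group(0), relevance)
    # Drop title hits nested inside an earlier, longer title match.
    starts = sorted(hits)
    kept: list[tuple[int, int, str, str]] = []
    cursor = -1
    for s in starts:
        e, title, relevance = hits[s]
        if s < cursor:
            continue
        kept.append((s, e, title, relevance))
        cursor = e
    sections: list[Section] = []
    if not kept:
        if text:
            sections.append(Section(title="", span_norm=(0, len(text)), relevance="relevant"))
        return sections
    first_start = kept[0][0]
    if first_start > 0:
        sections.append(Section(title="", span_norm=(0, first_start), relevance="relevant"))
    for i, (s, _e, title, relevance) in enumerate(kept):
        end = kept[i + 1][0] if i + 1 < len(kept) else len(text)
        sections.append(Section(title=title, span_norm=(s, end), relevance=relevance))
    return sections


def section_at(sections: list[Section], pos: int) -> Optional[Section]:
    """Section containing normalized position ``pos`` (None if uncovered)."""
    for sec in sections:
        if sec.span_norm[0] <= pos < sec.span_norm[1]:
            return sec
    return None
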