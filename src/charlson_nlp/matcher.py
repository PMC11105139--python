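"""Rule-based NER: regex-dictionary matching, exclusions, severity statuses.

One :class:`CompiledMatcher` per condition.  All patterns match on the
normalized text; resulting spans are reported on the raw text through the
normalization offset map.  Overlapping matches of the same condition are
resolved longest-match-first, then leftmost.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .preprocessing import NormalizedText, Section, Token, section_at, tokenize
from .types import ConditionDefinition, Mention, SeverityRule

#: Punctuation ending the sentence-bounded scope of a severity rule.
SENTENCE_TERMINATORS = frozenset({".", ";", "!", "?"})


@dataclass
class CompiledMatcher:
    condition_id: str
    definition: ConditionDefinition
    inclusion: list[tuple[re.Pattern, Optional[str]]]
    exclusion: list[re.Pattern]
    severity_rules: list[tuple[re.Pattern, SeverityRule]]
    window_tokens: int


def compile_matchers(definitions: Sequence[ConditionDefinition]) -> list[CompiledMatcher]:
    """Compile validated definitions into per-condition matchers."""
    matchers = []
    for d in definitions:
        matchers.append(
            CompiledMatcher(
                condition_id=d.condition_id,
                definition=d,
                inclusion=[(re.compile(p), hint) for p, hint in d.patterns],
                exclusion=[re.compile(p) for p in d.exclusion_patterns],
                severity_rules=[(re.compile(r.pattern), r) for r in d.severity_rules],
                window_tokens=d.window_tokens,
            )
        )
    return matchers


def token_range(tokens: Sequence[Token], norm_span: tuple[int, int]) -> tuple[int, int]:
    """Indices (first, last inclusive) of tokens overlapping a norm span."""
    s, e = norm_span
    first = last = None
    for t in tokens:
        ts, te = t.span_norm
        if ts < e and s < te:
            if first is None:
                first = t.index
            last = t.index
    if first is None:
        raise ValueError(f"no token overlaps span {norm_span}")
    return first, last


def _snippet_span_norm(
    tokens: Sequence[Token], tok_range: tuple[int, int], window: int
) -> tuple[int, int]:
    lo = max(0, tok_range[0] - window)
    hi = min(len(tokens) - 1, tok_range[1] + window)
    return (tokens[lo].span_norm[0], tokens[hi].span_norm[1])


def extract_mentions(
    note_id: str,
    norm_text: NormalizedText,
    matchers: Sequence[CompiledMatcher],
    tokens: Optional[Sequence[Token]] = None,
) -> list[Mention]:
    """Run every inclusion pattern; return mentions with raw-text spans.

    Returned mentions have no status and empty qualifiers.  Internal
    bookkeeping (normalized span, token range, pattern status hint) is kept
    on private attributes consumed by the downstream stages.
    """
    if tokens is None:
        tokens = tokenize(norm_text)
    mentions: list[Mention] = []
    for matcher in matchers:
        hits: list[tuple[int, int, Optional[str]]] = []
        for rx, hint in matcher.inclusion:
            for m in rx.finditer(norm_text.norm):
                if m.start() < m.end():
                    hits.append((m.start(), m.end(), hint))
        # Longest match first, leftmost on ties; drop overlaps.
        hits.sort(key=lambda h: (-(h[1] - h[0]), h[0]))
        selected: list[tuple[int, int, Optional[str]]] = []
        for s, e, hint in hits:
            if all(e <= s2 or e2 <= s for s2, e2, _ in selected):
                selected.append((s, e, hint))
        selected.sort()
        for k, (s, e, hint) in enumerate(selected):
            tr = token_range(tokens, (s, e))
            snip_norm = _snippet_span_norm(tokens, tr, matcher.window_tokens)
            mention = Mention(
                mention_id=f"{note_id}:{matcher.condition_id}:{k}",
                note_id=note_id,
                condition_id=matcher.condition_id,
                span=norm_text.raw_span(s, e),
                snippet_span=norm_text.raw_span(*snip_norm),
            )
            mention._norm_span = (s, e)  # type: ignore[attr-defined]
            mention._tok_range = tr  # type: ignore[attr-defined]
            mention._status_hint = hint  # type: ignore[attr-defined]
            mentions.append(mention)
    return mentions


def apply_exclusions(
    mentions: Sequence[Mention],
    norm_text: NormalizedText,
    matchers: Sequence[CompiledMatcher],
    sections: Sequence[Section],
) -> list[Mention]:
    """Flag mentions hit by an exclusion pattern or lying in special sections.

    Overlap with an exclusion match of the same condition, or position inside
    an irrelevant section, sets the ``generic_fp`` qualifier and discards the
    mention.  Position inside a family-history section adds the ``family``
    qualifier instead.
    """
    by_condition = {m.condition_id: m for m in matchers}
    excl_spans: dict[str, list[tuple[int, int]]] = {}
    for matcher in matchers:
        spans = []
        for rx in matcher.exclusion:
            spans.extend((m.start(), m.end()) for m in rx.finditer(norm_text.norm))
        excl_spans[matcher.condition_id] = spans
    for mention in mentions:
        s, e = mention._norm_span  # type: ignore[attr-defined]
        if mention.condition_id in by_condition:
            for xs, xe in excl_spans[mention.condition_id]:
                if s < xe and xs < e:
                    mention.qualifiers.add("generic_fp")
                    mention.discarded = True
                    break
        sec = section_at(list(sections), s)
        if sec is not None:
            if sec.relevance == "irrelevant":
                mention.qualifiers.add("generic_fp")
                mention.discarded = True
            elif sec.relevance == "family_history":
                mention.qualifiers.add("family")
                mention.discarded = True
    return list(mentions)


def _rule_in_scope(
    tokens: Sequence[Token],
    entity_range: tuple[int, int],
    match_span: tuple[int, int],
    window_words: int,
) -> bool:
    """True iff a severity-rule match lies within the token window of the
    entity with no sentence terminator in between."""
    try:
        m_first, m_last = token_range(tokens, match_span)
    except ValueError:
        return False
    e_first, e_last = entity_range
    if m_last < e_first:  # match before entity
        gap = range(m_last + 1, e_first)
        dist = e_first - m_last - 1
    elif m_first > e_last:  # match after entity
        gap = range(e_last + 1, m_first)
        dist = m_first - e_last - 1
    else:  # overlapping the entity itself
        return True
    if dist > window_words:
        return False
    return not any(tokens[i].surface in SENTENCE_TERMINATORS for i in gap)


def assign_status(
    mention: Mention,
    norm_text: NormalizedText,
    matcher: CompiledMatcher,
    tokens: Optional[Sequence[Token]] = None,
) -> Mention:
    """Deduce the severity status of a mention of a statused condition.

    Candidates come from severity-rule matches in scope and from the matched
    pattern's status hint; the most severe candidate wins.  With no candidate
    the least severe status applies.  No-op for binary conditions.
    """
    definition = matcher.definition
    if not definition.statuses:
        return mention
    if tokens is None:
        tokens = tokenize(norm_text)
    entity_range = getattr(mention, "_tok_range", None)
    if entity_range is None:
        entity_range = token_range(tokens, mention._norm_span)  # type: ignore[attr-defined]
    candidates: list[str] = []
    hint = getattr(mention, "_status_hint", None)
    if hint is not None:
        candidates.append(hint)
    s, e = mention._norm_span  # type: ignore[attr-defined]
    lo = max(0, s - 400)
    hi = min(len(norm_text.norm), e + 400)
    for rx, rule in matcher.severity_rules:
        for m in rx.finditer(norm_text.norm, lo, hi):
            if _rule_in_scope(tokens, entity_range, (m.start(), m.end()), rule.window_words):
                candidates.append(rule.status)
                break
    if candidates:
        mention.status = max(candidates, key=definition.severity_index)
    else:
        mention.status = definition.default_status
    return mention


def assign_statuses(
    mentions: Sequence[Mention],
    norm_text: NormalizedText,
    matchers: Sequence[CompiledMatcher],
    tokens: Optional[Sequence[Token]] = None,
) -> list[Mention]:
    if tokens is None:
        tokens = tokenize(norm_text)
    by_condition = {m.condition_id: m for m in matchers}
    for mention in mentions:
        matcher = by_condition.get(mention.condition_id)
        if matcher is not None and matcher.definition.statuses:
            assign_status(mention, norm_text, matcher, tokens)
    return list(mentions)
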