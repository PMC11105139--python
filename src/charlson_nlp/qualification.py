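"""Rule-based entity qualification: negation, hypothesis, family relation.

NegEx-style semantics: a cue qualifies an entity iff it occurs within a
class-specific token window on the proper side of the entity with no scope
terminator between cue and entity.  Negation distinguishes preceding from
following cues; hypothesis and family cues act on either side.  A mention
inside a family-history section is family-related regardless of cues.
"""
from __future__ import annotations

from typing import Optional, Sequence

from .config import CueLexicon
from .matcher import token_range
from .preprocessing import Section, Token, section_at, tokenize
from .types import Mention


def _cue_token_seqs(phrases: Sequence[str]) -> list[tuple[str, ...]]:
    return [tuple(t.surface for t in tokenize(p)) for p in phrases]


def _occurrences(tokens: Sequence[Token], cue: tuple[str, ...]) -> list[tuple[int, int]]:
    """(first, last inclusive) token indices of each cue occurrence."""
    n, k = len(tokens), len(cue)
    out = []
    for i in range(n - k + 1):
        if all(tokens[i + j].surface == cue[j] for j in range(k)):
            out.append((i, i + k - 1))
    return out


def _blocked(tokens: Sequence[Token], lo: int, hi: int, terminators: frozenset) -> bool:
    """Any terminator token strictly between indices lo and hi (exclusive)?"""
    return any(tokens[i].surface in terminators for i in range(lo + 1, hi))


def _entity_range(
    mention: Mention, tokens: Sequence[Token], entity_range: Optional[tuple[int, int]]
) -> tuple[int, int]:
    if entity_range is not None:
        return entity_range
    rng = getattr(mention, "_tok_range", None)
    if rng is not None:
        return rng
    norm_span = getattr(mention, "_norm_span", None)
    if norm_span is None:
        raise ValueError(
            "mention carries no token range; pass entity_range explicitly"
        )
    return token_range(tokens, norm_span)


def _cue_in_scope(
    tokens: Sequence[Token],
    entity: tuple[int, int],
    cues: Sequence[tuple[str, ...]],
    window: int,
    terminators: frozenset,
    side: str,
) -> bool:
    e_first, e_last = entity
    for cue in cues:
        for c_first, c_last in _occurrences(tokens, cue):
            if side in ("before", "both") and c_last < e_first:
                dist = e_first - c_last - 1
                if dist <= window and not _blocked(tokens, c_last, e_first, terminators):
                    return True
            if side in ("after", "both") and c_first > e_last:
                dist = c_first - e_last - 1
                if dist <= window and not _blocked(tokens, e_last, c_first, terminators):
                    return True
    return False


def detect_negation(
    mention: Mention,
    tokens: Sequence[Token],
    lexicon: CueLexicon,
    entity_range: Optional[tuple[int, int]] = None,
) -> bool:
    entity = _entity_range(mention, tokens, entity_range)
    window = lexicon.scope_window_tokens["negation"]
    terminators = frozenset(lexicon.scope_terminators)
    return _cue_in_scope(
        tokens, entity, _cue_token_seqs(lexicon.negation_preceding), window, terminators, "before"
    ) or _cue_in_scope(
        tokens, entity, _cue_token_seqs(lexicon.negation_following), window, terminators, "after"
    )


def detect_hypothesis(
    mention: Mention,
    tokens: Sequence[Token],
    lexicon: CueLexicon,
    entity_range: Optional[tuple[int, int]] = None,
) -> bool:
    entity = _entity_range(mention, tokens, entity_range)
    return _cue_in_scope(
        tokens,
        entity,
        _cue_token_seqs(lexicon.hypothesis),
        lexicon.scope_window_tokens["hypothesis"],
        frozenset(lexicon.scope_terminators),
        "both",
    )


def detect_family(
    mention: Mention,
    tokens: Sequence[Token],
    sections: Sequence[Section],
    lexicon: CueLexicon,
    entity_range: Optional[tuple[int, int]] = None,
) -> bool:
    norm_span = getattr(mention, "_norm_span", None)
    if norm_span is not None:
        sec = section_at(list(sections), norm_span[0])
        if sec is not None and sec.relevance == "family_history":
            return True
    entity = _entity_range(mention, tokens, entity_range)
    return _cue_in_scope(
        tokens,
        entity,
        _cue_token_seqs(lexicon.family),
        lexicon.scope_window_tokens["family"],
        frozenset(lexicon.scope_terminators),
        "both",
    )


def qualify_rule_based(
    mentions: Sequence[Mention],
    tokens: Sequence[Token],
    sections: Sequence[Section],
    lexicon: CueLexicon,
) -> list[Mention]:
    """Set qualifier flags and the discard decision on every mention.

    Only qualifier fields are touched; spans, conditions and statuses are
    left untouched.  ``discarded`` is true iff any qualifier (including a
    pre-set ``generic_fp``) applies.
    """
    for m in mentions:
        if detect_negation(m, tokens, lexicon):
            m.qualifiers.add("negated")
        if detect_hypothesis(m, tokens, lexicon):
            m.qualifiers.add("hypothetical")
        if detect_family(m, tokens, sections, lexicon):
            m.qualifiers.add("family")
        m.discarded = bool(m.qualifiers)
    return list(mentions)
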