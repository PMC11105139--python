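"""End-to-end drivers chaining preprocessing, NER, qualification, aggregation."""
from __future__ import annotations

from typing import Optional, Sequence

from .aggregation import aggregate_stay
from .config import PipelineConfig
from .matcher import apply_exclusions, assign_statuses, compile_matchers, extract_mentions
from .preprocessing import detect_sections, normalize_text, tokenize
from .qualification import qualify_rule_based
from .qualifier_ml import LabeledSnippet, SnippetQualifier, qualify_learned
from .types import Mention, Note, StayPrediction


def annotate_note(
    note: Note,
    config: PipelineConfig,
    matchers=None,
    mode: str = "rule_based",
    model: Optional[SnippetQualifier] = None,
) -> list[Mention]:
    """Extract, exclude, status-assign and qualify the mentions of one note."""
    if matchers is None:
        matchers = compile_matchers(config.definitions)
    nt = normalize_text(note.text)
    tokens = tokenize(nt)
    sections = detect_sections(nt, config.section_lexicon)
    mentions = extract_mentions(note.note_id, nt, matchers, tokens)
    mentions = apply_exclusions(mentions, nt, matchers, sections)
    mentions = assign_statuses(mentions, nt, matchers, tokens)
    if mode == "rule_based":
        mentions = qualify_rule_based(mentions, tokens, sections, config.cue_lexicon)
    elif mode == "learned":
        if model is None:
            raise ValueError("learned qualification requires a trained model")
        window = 8
        snippets = []
        for m in mentions:
            first, last = m._tok_range  # type: ignore[attr-defined]
            lo = max(0, first - window)
            hi = min(len(tokens) - 1, last + window)
            snippets.append(
                LabeledSnippet(
                    tokens=tuple(t.surface for t in tokens[lo : hi + 1]),
                    entity_range=(first - lo, last - lo),
                )
            )
        # exclusion-based discards (care sites, irrelevant sections) stand
        flagged = [m.discarded for m in mentions]
        mentions = qualify_learned(mentions, snippets, model)
        for m, was_flagged in zip(mentions, flagged):
            m.discarded = m.discarded or was_flagged
    else:
        raise ValueError(f"unknown qualification mode {mode!r}")
    return mentions


def run_nlp_pipeline(
    notes: Sequence[Note],
    config: PipelineConfig,
    mode: str = "rule_based",
    model: Optional[SnippetQualifier] = None,
) -> tuple[list[Mention], list[StayPrediction]]:
    """Annotate a corpus and aggregate mentions to stay-level predictions.

    Mentions from all notes of one stay are pooled (union) before
    aggregation.
    """
    matchers = compile_matchers(config.definitions)
    all_mentions: list[Mention] = []
    per_stay: dict[str, list[Mention]] = {}
    for note in notes:
        mentions = annotate_note(note, config, matchers, mode=mode, model=model)
        all_mentions.extend(mentions)
        per_stay.setdefault(note.stay_id, []).extend(mentions)
    predictions = [
        aggregate_stay(stay_id, ms, config.definitions, source="nlp")
        for stay_id, ms in per_stay.items()
    ]
    return all_mentions, predictions
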