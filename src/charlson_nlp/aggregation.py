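"""Stay-level aggregation, Charlson comorbidity index, prevalence estimates.

Aggregation: a condition is present at the stay level iff at least one
non-discarded mention remains; for statused conditions the most severe
status among kept mentions wins (a mention with no status counts as least
severe).  The CCI is the weighted sum over the 16 index conditions;
tobacco and alcohol never contribute.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .types import (
    ABSENT,
    NON_CCI_CONDITIONS,
    PRESENT,
    ConditionDefinition,
    Mention,
    StayPrediction,
)


def aggregate_stay(
    stay_id: str,
    mentions: Iterable[Mention],
    definitions: Sequence[ConditionDefinition],
    source: str = "nlp",
) -> StayPrediction:
    """Collapse kept mentions of one stay into a per-condition prediction.

    Discarded mentions are filtered here, so callers may pass the full list.
    Idempotent and order-independent over the mention list.
    """
    by_id = {d.condition_id: d for d in definitions}
    best: dict[str, Optional[str]] = {}
    for m in mentions:
        if m.discarded:
            continue
        d = by_id[m.condition_id]
        if m.condition_id not in best:
            best[m.condition_id] = m.status
        else:
            cur = best[m.condition_id]
            if d.severity_index(m.status) > d.severity_index(cur):
                best[m.condition_id] = m.status
    conditions: dict[str, str] = {}
    for d in definitions:
        if d.condition_id not in best:
            conditions[d.condition_id] = ABSENT
        else:
            status = best[d.condition_id]
            if d.statuses:
                conditions[d.condition_id] = status if status is not None else d.default_status
            else:
                conditions[d.condition_id] = PRESENT
    return StayPrediction(stay_id=stay_id, source=source, conditions=conditions)


def aggregate_stays(
    mentions: Iterable[Mention],
    note_to_stay: dict[str, str],
    definitions: Sequence[ConditionDefinition],
    source: str = "nlp",
    stay_ids: Optional[Sequence[str]] = None,
) -> list[StayPrediction]:
    """Aggregate mentions across all notes of each stay (union of mentions)."""
    per_stay: dict[str, list[Mention]] = {s: [] for s in (stay_ids or [])}
    for m in mentions:
        per_stay.setdefault(note_to_stay[m.note_id], []).append(m)
    return [
        aggregate_stay(stay, ms, definitions, source=source)
        for stay, ms in per_stay.items()
    ]


def compute_cci(
    prediction: StayPrediction, definitions: Sequence[ConditionDefinition]
) -> int:
    """Charlson comorbidity index of one stay prediction.

    Statused conditions use the status-specific weight; a statused condition
    reported as bare "present" falls back to the least-severe weight.
    Raises if the weight table does not cover a present condition's status.
    """
    score = 0
    by_id = {d.condition_id: d for d in definitions}
    for condition_id, value in prediction.conditions.items():
        if value == ABSENT:
            continue
        if condition_id in NON_CCI_CONDITIONS:
            continue
        d = by_id[condition_id]
        weights = d.cci_weight or {}
        if d.statuses:
            status = value if value != PRESENT else d.default_status
            if status not in weights:
                raise ValueError(
                    f"CCI weight table covers {sorted(weights)} but "
                    f"{condition_id} is present with status {status!r}"
                )
            score += weights[status]
        else:
            if "any" not in weights:
                raise ValueError(f"CCI weight table missing {condition_id}")
            score += weights["any"]
    return score


def estimate_prevalence(
    predictions: Sequence[StayPrediction], condition_id: str
) -> float:
    """Fraction of stays with the condition present."""
    if not predictions:
        raise ZeroDivisionError("prevalence undefined on an empty stay set")
    hits = sum(1 for p in predictions if p.is_present(condition_id))
    return hits / len(predictions)


def prevalence_gap(
    a: Sequence[StayPrediction],
    b: Sequence[StayPrediction],
    condition_ids: Sequence[str],
) -> float:
    """Mean absolute per-condition prevalence difference between two sources."""
    gaps = [
        abs(estimate_prevalence(a, c) - estimate_prevalence(b, c))
        for c in condition_ids
    ]
    return sum(gaps) / len(gaps)
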